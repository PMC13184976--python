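# Packaged end-to-end demo: simulate a small halogen-bond-capable hairpin
# ensemble (Br...O donor/acceptor pair), then run the two-stage analysis.
#
#   hairpinxb simulate --config examples/demo.yaml --output-dir demo_out
#   hairpinxb run-full --config demo_out/run.yaml --out demo_out/report.json
#
# (`simulate` writes the pool/restraint tables under output_dir; point the
# run config's pool/noe_series/j_table/rdc_table keys at those files.)
seed: 5
output_dir: demo_out
simulate:
  n_folded: 4
  n_unfolded: 4
  n_xb_enrich: 3
  dihedral_jitter: 10.0
  folded_fraction: 0.5
  donor_element: Br
  acceptor_element: O
  noe_rate_rel: 0.05   # 5% relative noise on NOE buildup rates
  j_hz: 0.3            # 0.3 Hz on 3J couplings
  rdc_hz: 0.3          # 0.3 Hz on RDCs
fit:
  noe_rate_rel_error: 0.05   # propagate the known rate noise into weights
energetics:
  reference_folded_percent: 22.0   # halogen-free reference compound
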