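# hairpinxb

Ensemble-based NMR analysis for quantifying a single weak noncovalent
interaction — here a halogen bond — through its effect on β-hairpin
folding in aqueous solution.

A weak halogen bond (1–3 kJ mol⁻¹) between a halo-imidazole donor
(C–X, X = Br/I) and a (thio)ether acceptor (Y = O/S) is far too weak to
detect by chemical-shift titration at millimolar concentration. Embedding
the donor/acceptor pair across the two strands of a cooperatively folding
12-residue β-hairpin (D-Pro–Gly type II′ turn) amplifies the interaction:
the bond's strength shifts the folded population, and population-averaged
NMR observables report on that shift. This package implements the full
analysis chain as a tested, reusable library plus CLI:

1. **Backbone stage** — NOE buildup rates σ are calibrated to distances by
   internal referencing to the geminal methylene pair,
   r = r_ref·(σ_ref/σ)^(1/6) with r_ref = 1.78 Å, and ³J(NH–Hα) couplings
   map to φ through the Karplus curve J = A·cos²θ + B·cosθ + C
   (θ = φ − 60°). Conformer populations **p** are deconvoluted by
   non-negative least squares in ⟨r⁻⁶⟩-transformed space:
   min ‖W(Ap − y)‖² + λ²(Σpₖ − 1)², p ≥ 0. The folded fraction is the
   summed weight of conformers passing the hairpin classifier (type II′
   turn torsions ±30°, mean cross-strand Cα–Cα ≤ 6 Å, ≥ 4 of 6
   interstrand H-bonds).
2. **Side-chain stage** — ¹H,¹³C RDCs (D = T_strong − T_weak) determine a
   common Saupe alignment tensor **S** (5 components, SVD fit, ≥ 5
   independent RDCs) and conformer populations by alternating
   optimization, with the Cornilescu quality factor
   Q = rms(D_obs − D_calc)/rms(D_obs) (Q < 0.3 good, < 0.4 acceptable)
   and the design-matrix condition number (CN < 30 robust) as
   diagnostics. Conformers with d(X···Y) ≤ ΣvdW and ∠(C–X···Y) > 120°
   count as halogen-bonded.
3. **Energetics** — folded-population shifts convert to stabilization
   energies via ΔΔG = −RT·ln(p/p_ref), and relative DFT dimer energies
   ΔΔE correlate against halogen-bonded populations.

Because real restraint tables for such systems live in supporting
information that is rarely machine-readable, the package ships a
synthetic-data module (`hairpinxb.synthetic`) that builds idealized
hairpin conformer pools with known ground truth — folded/unfolded
two-state mixtures, halogen-bond-constrained side-chain poses, and noisy
NOE/J/RDC tables — so every stage of the pipeline is validated by
parameter recovery.

## Worked example

```bash
hairpinxb simulate --config examples/demo.yaml --output-dir demo_out
```

writes a multi-model PDB pool (8 sampled conformers + 3
halogen-bond-constrained ones), NOE buildup series (7 mixing times,
100–700 ms), a ³J table, a 15-RDC table, and the generating ground truth.
Pointing the same config's `pool`/`noe_series`/`j_table`/`rdc_table` keys
at those files and running

```bash
hairpinxb run-full --config demo_out/run.yaml --out demo_out/report.json
```

produces (numbers from this exact config, seed 5):

| quantity | fitted | ground truth |
|---|---|---|
| folded β-hairpin | 65.8 % | 65.0 % |
| halogen-bonded (XB) | 37.3 % | 38.7 % |
| Q factor | 0.012 (“good”) | — |
| condition number | 5.5 | — |
| ΔΔG vs 22 %-folded reference | −2.72 kJ mol⁻¹ | — |
| fold increase | 2.99 (“3-fold”) | — |

The backbone fit used 81 NOE-derived distances and 11 couplings; the
side-chain fit used the 15 RDCs. A ΔΔG near −2.7 kJ mol⁻¹ with a
three-fold folding increase is exactly the regime where a single weak
halogen bond operates, and the low Q/CN indicate a trustworthy tensor
fit.

The library surface mirrors the pipeline: see
`hairpinxb.deconvolution.fit_populations`,
`hairpinxb.rdc.fit_tensor_and_populations`,
`hairpinxb.classify.classify_folded` / `classify_xb`, and
`hairpinxb.energetics.boltzmann_ddg`. `docs/methods.md` documents the
model, defaults, and limitations.

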