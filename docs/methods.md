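# Methods

## The model system and what the package computes

The analysis targets a single weak halogen bond (XB) embedded across the
antiparallel strands of a 12-residue β-hairpin nucleated by a
D-Pro–Gly type II′ turn. The donor is a halo-imidazole side chain
(covalent C–X bond, X = Br or I), the acceptor an ether/thioether chain
(Y = O or S); the interaction-free reference replaces them with C–H and
CH₂. Because the bond is worth only a few kJ mol⁻¹, it is quantified
indirectly: the hairpin's folded population rises when the interstrand
contact is attractive, and population-averaged NMR observables (NOEs,
³J couplings, RDCs) report on that population. The package implements
the two-stage deconvolution of those observables into conformer
populations, the geometric classification of folded and halogen-bonded
conformers, and the Boltzmann conversion of population shifts into
energies — exercised end-to-end on synthetic ensembles with known
ground truth.

## Backbone stage: NOE/J population deconvolution

**Distance calibration.** NOE cross-peak intensities grow linearly with
mixing time in the initial-rate regime; the buildup rate σ of an
isolated spin pair scales with r⁻⁶. Rates are fitted by ordinary least
squares over the seven mixing times (0.100–0.700 s) with a free
intercept (a `through_origin` flag exists; the free intercept is robust
to baseline offsets). Distances follow by internal referencing to the
geminal methylene pair at r_ref = 1.78 Å: r = r_ref (σ_ref/σ)^{1/6}.

**Karplus map.** ³J(NH–Hα) = A cos²θ + B cosθ + C with θ = φ + phase;
defaults A = 6.51, B = −1.76, C = 1.60 Hz, phase = −60°, a standard
HN–Hα parameterization. The coefficients are configurable because
published sets differ at the few-tenths-of-Hz level and the choice is a
genuine degree of freedom of any reanalysis.

**Linear model.** Population averaging is linear in r⁻⁶ and in J, so
NOE rows enter the design matrix as rₖ⁻⁶ per conformer k with the
observation r_obs⁻⁶, and J rows as Karplus values of each conformer's
φ. Errors propagate into the transformed space as Δ(r⁻⁶) = 6r⁻⁷Δr.
When the relative uncertainty of the buildup rates is known, the
distance error is Δr/r = (Δσ/σ)/6 — an order of magnitude sharper than
the 10 %-of-distance fallback used when no error information exists.
This matters: with 10 % distance errors the NOE block is down-weighted
~70× in r⁻⁶ space and the fit becomes dominated by coupling noise.

**Solver.** Weighted non-negative least squares with a soft unit-sum
row of strength λ = 10 × the largest row weight, then exact
renormalization. Collinear columns (near-duplicate conformers) are not
merged; rank deficiency or a weighted condition number above 10⁸ sets a
flag and the class sums (e.g. total folded weight) remain meaningful
even when the within-class split is arbitrary. Residuals are reported
back in natural units (Å, Hz). A residual-resampling bootstrap
(deterministic per seed) provides the spread of the folded fraction.

## Side-chain stage: RDC tensor and XB populations

An RDC of a C–H bond with unit direction **b** is linear in the five
independent components of the traceless symmetric Saupe matrix; the
dipolar prefactor (gyromagnetic ratios, effective bond length) is
absorbed into the tensor scale, since only relative geometry matters
for populations and Q. One common tensor is shared by all conformers —
with 15 observables, per-conformer tensors would be hopelessly
unidentifiable. For fixed populations the tensor is the SVD
least-squares solution on the population-averaged, error-weighted
design matrix; its condition number (largest/smallest singular value)
gauges orientational coverage, with CN ≥ 30 flagged unreliable. For a
fixed tensor the populations are an NNLS problem with the same
unit-sum device. The joint fit alternates the two updates, accepting
steps while Q decreases, stopping at |ΔQ| < 10⁻¹² or 200 iterations.
The Q tolerance is deliberately far below the 10⁻⁶ one might pick for
noisy data because the noiseless recovery property (Q → 0 exactly)
is part of the package's validation contract and the iterations are
cheap. The bilinear problem can have local minima, so a deterministic
set of starts (uniform, class-vertex, fixed-seed Dirichlet) is tried
and the lowest-Q solution kept.

**Staging.** Fitting backbone and side chains simultaneously is
counterproductive for a flexible dodecapeptide, so the pipeline
determines backbone populations first and then resolves side-chain
orientation against RDCs. Two modes are exposed: `free` refits all
populations from RDCs alone; `staged` (default) restricts the pool to
conformers the backbone fit populated (plus all XB-classified poses)
and pins the total folded weight at the backbone-stage value through a
soft constraint row.

**Identifiability limits.** Of the 15 RDCs (12 Cα–Hα + 3 side-chain
C–H), only three discriminate side-chain pose, so the XB population is
the weakest-determined number in the pipeline. On noiseless data with a
small pool of geometrically distinct conformers the XB share is
recovered exactly; with 0.3 Hz RDC noise, large pools (≥ 20 conformers),
or seeds where an unconstrained pose mimics the RDC signature of a
constrained one, the XB percentage can deviate by ±10 points or more
while Q stays near zero. The packaged demo uses a small pool where the
fit is well-posed; the limitation is inherent to the observable count,
not to the solver.

## Geometric classifiers

* **Folded hairpin** (all three required): turn residues within ±30° of
  the canonical type II′ torsions (+60°, −120°)/(−80°, 0°) with angular
  wrap-around; mean cross-strand Cα–Cα distance over the five strand
  pairs ≤ 6.0 Å; at least 4 of the 6 designated interstrand N–H···O=C
  bonds formed, where an H-bond means donor–acceptor heavy-atom
  distance ≤ 3.5 Å and D–H···A angle ≥ 120°. The H-bond geometry rule
  and the turn window are package choices (standard values); the 6 Å
  and 4-of-6 thresholds are the field's criteria for this system.
* **Halogen bond**: d(X···Y) ≤ r_vdW(X) + r_vdW(Y) (inclusive at
  equality) and ∠(C–X···Y) > 120° (strict) — the near-linear σ-hole
  geometry. Bondi radii are the default table (H 1.20, C 1.70, N 1.55,
  O 1.52, S 1.80, Br 1.85, I 1.98 Å); the table is swappable and is
  self-consistent with the 90/94/87/91 % contact ratios of the
  DFT-optimized model dimers. Donors outside {Br, I} raise in strict
  mode and classify False in permissive mode.

## The synthetic ensemble generator

The generator emulates the conformational-search + NMR-acquisition
stages, not their physics. Toy residues carry an alanine-like backbone
(N, H, Cα, Hα, C′, O); only the two interaction side chains have full
heavy-atom detail (imidazole ring with C–X; CH₂–CH₂–Y–CH₃ chain). The
two geminal Hα of the turn glycine sit exactly 1.78 Å apart so the NOE
calibration is bias-free by construction.

* **Folded template.** Backbone torsions are built by internal
  coordinates (ideal bond lengths/angles, trans peptide). Strand
  torsions start from ideal antiparallel-β values and are refined once
  by penalty optimization (H-bond distances → 2.95 Å and angles,
  sheet-register Cα targets, steric floor, small regularizer) so that
  all six designated H-bonds form. The solution for the default
  geometry is stored as constants; other sizes re-optimize on the fly.
  Side-chain torsions are posed by grid search + simplex refinement to
  an XB contact (d ≈ 0.9 ΣvdW, near-linear angle). Construction and
  classification are independent code paths; the template is verified
  against the classifier and a failure raises, never silently relabels.
* **Pools.** Folded conformers are Gaussian torsion jitters of the
  template (defaults: 8° backbone, 40° side chain), re-jittered until
  they still classify folded; unfolded conformers draw strand torsions
  uniformly from the β/PPII basin (φ ∈ (−180°, −55°), ψ ∈ (60°, 180°)),
  keep the canonical turn, and are rejected on steric clash
  (< 0.7 ΣvdW between residues ≥ 2 apart) — the unfolded path never
  consults the classifier, so generator/classifier agreement is a real
  property. Ground-truth populations split the folded fraction
  (default 0.5, the design point of the model system) evenly within
  each class.
* **XB enrichment.** Because standard force fields do not model halogen
  bonding, pools are enriched with conformers whose side-chain torsions
  are resampled and locally refined into the XB-allowed region, with
  randomized contact targets for diversity. Redundant appends are
  removed at a 1.5 Å RMSD cutoff measured over the resampled side-chain
  heavy atoms after backbone superposition — at toy scale, whole-
  molecule RMSD would bury genuine pose differences under the 44
  unchanged backbone atoms and no set of five mutually distinct poses
  would survive.
* **Observables.** NOE: every backbone NH/Hα proton pair whose
  population-averaged effective distance ⟨r⁻⁶⟩^{−1/6} is within a 5 Å
  detection horizon gets a seven-point buildup series; Gaussian noise
  is applied to the rate (default 5 % relative), matching how
  integration error propagates in practice. J: population-averaged
  Karplus values, 0.3 Hz noise. RDC: population-averaged Saupe
  projections of a randomly drawn tensor scaled so the largest
  |D| ≈ 13 Hz (the compressed-gel range), 0.3 Hz noise. Everything is a
  pure function of (inputs, seed).

**What the generator does not emulate:** force-field energetics and
realistic conformational diversity (jittered templates are far more
self-similar than a Monte Carlo search output), spin diffusion and
multi-spin NOE effects, solvent-suppression artifacts, peak overlap,
dynamic averaging of the alignment tensor, and side chains on the
non-interacting residues. Passing recovery tests therefore demonstrates
the correctness of the fitting machinery under the stated noise model,
not the accuracy of the method on real spectra.

## Energetics

ΔΔG = −RT ln(p/p_ref) by default (T = 298.15 K, R = 8.314 J mol⁻¹ K⁻¹);
an odds-ratio convention −RT ln[(p/(1−p))/(p_ref/(1−p_ref))] is
available. The population-ratio convention is the default because it
reproduces the expected 1–2 kJ mol⁻¹ (weaker XBs) and ≤ 3 kJ mol⁻¹
(I···S) bands from folded populations of 40–65 % against a 22 %
reference. The often-quoted local sensitivity ("~15 % folding change
per kJ mol⁻¹") is not assumed; `local_sensitivity` reports the computed
derivative 100·p/RT (or 100·p(1−p)/RT), which spans roughly 9–26 %/kJ
mol⁻¹ over the relevant population range. DFT dimer energies are inputs
only; `relative_energies` performs the reference subtraction and
`correlation_report` gives Pearson and Spearman coefficients with an
explicit caveat that the energy–population relation is monotone but
need not be linear.

## Numerical choices and degenerate inputs

* Dihedrals follow the IUPAC sign convention on (−180°, 180°];
  angular comparisons wrap around.
* Coincident atoms, zero-length bond vectors, all-zero designs,
  rank-deficient RDC geometries (< 5 independent bonds), and boundary
  folded fractions (0 or 1) raise typed exceptions rather than
  returning NaNs.
* The PDB dialect is MODEL/ATOM/HETATM/ENDMDL (via gemmi) with element
  symbols from the element column, falling back to the atom-name
  leading letters; XYZ is the concatenated-frame dialect and carries no
  residue information.
* Problem sizes used by the shipped validation runs: 20-conformer pools
  × 20 seeds for folded-fraction recovery (~30 s total), an
  11-conformer demo for the end-to-end run (~10 s including template
  construction). These sizes make the full validation cheap to re-run
  while keeping the fits honestly over-determined only where the data
  warrant it.
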