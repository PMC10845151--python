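# Methods

## The correction model

The quantity of interest is the zero-point-inclusive barrier height
BH = (E_TS + ZPE_TS) − (E_R + ZPE_R). We regress the correction
Δ = BH_high − BH_low on per-reaction descriptors and report corrected
barriers BH_low + Δ̂. Working on the difference rather than the barrier
itself means the model only has to capture the *systematic error* of the
cheap method, which is far smoother and smaller in magnitude than the
barrier landscape itself.

All energies are kcal/mol, frequencies cm⁻¹, orbital energies eV,
temperatures K. The supported element set is H, C, N, O.

## Graphs and structure comparison

Bonds: atoms i, j are bonded iff d_ij ≤ s·(r_i + r_j) with Cordero-type
covalent radii (H 0.31, C 0.76, N 0.71, O 0.66 Å) and scale s = 1.2
(configurable in [1.0, 1.5]). Distances below 0.5 Å are rejected as
unphysical overlaps.

Connectivity fingerprint: the sorted eigenvalues of A + diag(Z). Two
structures with equal element multisets and fingerprints equal within
1e−4 are taken to share connectivity. The spectrum is invariant under atom
permutation by similarity transform; the diagonal atomic numbers separate
graphs that differ only in element placement. Known blind spots, accepted
and documented: cospectral graph pairs and enantiomers (all eigenvalue
tests are reflection-invariant).

Conformation fingerprint: eigenvalues of the matrix with w_ij =
(r_i + r_j)/d_ij on **all** atom pairs and Z on the diagonal, compared at
tolerance 1e−3 (looser, because the structures being compared come from
different optimizers). The all-pairs form is a deliberate design choice:
weights restricted to bonded pairs are insensitive to torsions — two
rotamers share bond lengths to high accuracy after optimization — whereas
nonbonded inverse distances change strongly between conformers while
remaining rotation-, reflection- and permutation-invariant. The
bonded-only weighted matrix is still used where the *graph* is the object
of interest, namely the weighted Laplacian below.

## Curation flow

A raw record carries the outcome of the upstream quantum-chemistry steps:
a TS-optimization success flag, the two IRC endpoint geometries, and
low-level re-optimized copies of the endpoints and of the dataset
reactant/product. Screening proceeds: (1) failed TS optimization →
discard; (2) both direction assignments (forward endpoint ↔ reactant and
the swap) are tried against the connectivity fingerprints — if neither is
consistent for both ends, discard; ties break in favor of
forward ↔ reactant; (3) the matched assignment's re-optimized endpoint is
compared to the re-optimized dataset structure with the conformation
fingerprint; mismatch → discard. Reason codes partition the input exactly,
and swapping the two endpoints flips the direction assignment without
changing the decision.

## Descriptor families

- `rdkit.*`: every 2D descriptor of the cheminformatics library's standard
  list, as the signed difference X_P − X_R (an averaged variant is
  switchable so the combining rule is auditable). Descriptors that are
  invariant for mass-conserving reactions (MolWt, ExactMolWt,
  HeavyAtomMolWt, HeavyAtomCount, NumValenceElectrons) are reported as raw
  reactant values — a fixed declared list, not runtime equality testing,
  so column semantics never depend on the particular reaction. The
  partial-charge family, BCUT2D family and Ipc are excluded (undefined or
  overflow-prone on small radical species); the resulting roster size is
  logged at assembly and nothing downstream depends on it.
- `topol.*` on the TS graph: Randić connectivity Σ(d_i d_j)^(−1/2);
  spectral gap λ₁ = the lowest eigenvalue of the weighted Laplacian D − W
  above 1e−9 (zero when the TS splits into fragments); Estrada index
  Σ exp(μ_i) of the plain 0/1 adjacency; first Zagreb Σ d_i² (second
  Zagreb behind a flag); mean/max degree and edge count. Only λ₁ uses the
  distance-weighted matrix — it is the "3D tightness" measure — the
  counting indices stay on the unweighted graph.
- `bonds.*`: ±{HH, CH, CN, CO, HN, HO, CC, NN, OO, NO} formed/broken
  counts from the positional atom mapping (valid because curation
  guarantees IRC-connected structures; records violating it are rejected
  upstream as data errors).
- `pm7.*`: BH_low; e^−BH on the raw kcal/mol value (a unit-bearing
  exponent kept as a monotone re-coding, clamped below −50); |ν₁| of the
  unique imaginary TS mode (zero or multiple imaginary modes reject the
  record); the three pairwise ZPE differences among R/TS/P; Koopmans
  η = (ε_LUMO − ε_HOMO)/2 and α = −(ε_LUMO + ε_HOMO)/2 at the TS; the TS
  bond-order-matrix eigenvalues sorted descending and zero-padded to a
  fixed width (default 10) so feature vectors have constant length across
  molecule sizes; π_R^s − π_P^s self-polarizability difference; and the
  reaction energy E_P − E_R.

## Feature matrix and selection

Families are stacked in the fixed order rdkit, topol, bonds, pm7;
zero-variance columns are dropped with a log line; any non-finite entry is
an error naming the record and column. Collinearity pruning is a greedy
scan in column order dropping a column iff |Pearson r| with any retained
column exceeds 0.9; using |r| covers sign-flipped duplicates, and
keep-first tie-breaking makes the retained set reproducible. Correlations
are estimated on the training rows only and the selection applied
everywhere, to keep the test split out of every fitted quantity. The
filter is idempotent and monotone in the threshold. A reduced set
(default 49 features) is the top-k by tree-ensemble gain importance, ties
broken by column order.

## Models

Data are split 85/5/10 (train/validation/test) by a seeded permutation;
model selection uses k-fold CV on the training block.

- **Tree head (XGBoost)**: squared-error objective, `tree_method="exact"`,
  single-threaded for determinism. Hyperparameters come from a seeded
  random search over a small documented grid (depth {3,4,6,8}, learning
  rate {0.03,0.05,0.1}, trees {300,600,1200}, subsample {0.8,1}, column
  subsample {0.6,1}, min child weight {1,5}) scored by k-fold CV; the
  budget (number of sampled configurations, default 25) is the main cost
  knob and desk-scale runs use 4–6. The exact split rule matters: it
  places thresholds at midpoints between observed values, so an
  independent float64 re-traversal of the dumped trees routes every sample
  identically to the library (histogram-based splits can put thresholds
  exactly on data values and break this).
- **GP head**: inputs standardized, target centered; kernel
  DotProduct + C·Matérn(ν=5/2) + White, hyperparameters by marginal
  likelihood. The linear component is essential under many weakly
  informative inputs: a purely stationary isotropic kernel concentrates
  pairwise distances when most standardized dimensions carry no signal and
  collapses toward the mean predictor, while the dot-product term lets the
  marginal likelihood recover the dominant smooth trend and leaves the
  Matérn part for local structure. Cubic cost in n is capped by a seeded
  training subsample (default 1000). The posterior standard deviation is
  exposed; on the synthetic study its 90% intervals cover 85–95% of
  held-out points.
- **Multitask neural head**: a fully connected trunk (two hidden layers of
  128, ReLU, early stopping on a 10% validation fraction) with two linear
  outputs — the correction and the reaction energy — trained under equal
  squared-loss weights. Joint training acts as a regularizer; only the
  correction output is consumed downstream.

Corrected barriers are BH_low + Δ̂; evaluation reports MAE and the signed
error histogram on the test split (identical whether computed on Δ or on
the corrected barrier). Learning curves subsample the training pool at
given sizes with repeats against a fixed held-out test set.

## Attribution

Tree-head attributions are exact path-dependent TreeSHAP, re-implemented
over the parsed tree dump in float64 (numba-compiled, iterative rather
than recursive). The model's `predict` for this head uses the same float64
traversal, so Σ_j φ_ij + E[f] equals the prediction to ~1e−14 — the
library's native contributions accumulate in float32 and miss strict
additivity tolerances once ensembles grow to hundreds of trees. The
implementation is validated against the library's own TreeSHAP (agreement
at float32 level) and against an exhaustive-subset Shapley oracle with
cover-weighted conditional expectations on small trees (agreement at
1e−10). Non-tree heads fall back to a seeded permutation-Shapley estimate
whose background is the mean of the explained rows. Global rankings are
mean |attribution|, descending.

## RRHO thermochemistry

G(T) = E_elec + ZPE + H_corr(T) − T·S(T) with ideal-gas translation
(Sackur–Tetrode at 1 atm standard state), rigid-rotor rotation (principal
moments from the geometry; atom/linear/nonlinear cases; symmetry number,
default 1), harmonic vibrations (imaginary modes must be excluded by the
caller; `thermo_input_from_species` does this), and spin degeneracy.
Physical constants are pinned literals (CODATA 2018; 1 cm⁻¹ =
2.85914×10⁻³ kcal/mol) so results are bit-reproducible across library
versions. Frequency scaling is a plain multiplicative factor; the
reference level defaults to 0.9914 and the low level to 1.0 (a documented
alternative for PM7-style methods is 0.976). ΔG‡(T) = G(TS) − G(R),
batched at 300/500/1000 K. No hindered rotors, no quasi-RRHO damping, no
tunneling.

A note on the T → 0 limit: the thermal residual G − (E + ZPE) equals
−RT ln(q_trans·q_rot·q_el) and decays only as T·ln T, so at T = 1 K it is
of order 10⁻³ kcal/mol with a species-dependent sign; N₂ (q_tot(1 K) ≈ 1)
sits below 10⁻³ and is the reference case used in tests.

## Synthetic study conditions

The generator emulates the statistical shape of a curated gas-phase CHNO
dataset; it makes no attempt at chemically realistic potential-energy
surfaces — scalars are draws from documented distributions.

- Species: 2–7 heavy atoms drawn from {C, N, O}, hydrogens saturating the
  valences (C 4, N 3, O 2), a random spanning tree plus one optional ring
  (probability 0.3). Geometries are embedded by bonded springs toward
  covalent-radius sums plus soft-core nonbonded repulsion (L-BFGS from a
  BFS initial placement), retried until distance-based bond perception
  reproduces the intended adjacency exactly.
- Reactions: unimolecular; the product applies 1–3 degree-preserving
  double-edge swaps to the reactant graph (spectrally distinct from it),
  re-embedded from the reactant coordinates so the positional atom mapping
  is preserved. The TS geometry is the clash-free midpoint interpolation.
- Low-level scalars: energies N(0, 20²) kcal/mol; 3N−6 harmonic modes
  uniform on [200, 3500] cm⁻¹ with ZPE = Σ hcν/2; TSs carry exactly one
  imaginary mode, −uniform[400, 2000] cm⁻¹; HOMO ~ N(−9.5, 0.8²) eV with
  gaps uniform [6, 12] eV at minima and [1, 8] eV at TSs (hardness dips at
  the TS); bond orders ≈ 1 on bonds (≈ ½ for changing bonds at the TS)
  with mild noise; the low-level barrier is drawn uniform [5, 60] kcal/mol
  and the TS energy set from it by construction.
- Ground truth: Δ_true = −2.0 + 0.10·BH_low + 0.60·η_TS + 1.50·λ₁_TS +
  0.80·(+CH) − 0.70·(−CH), all five descriptors computed with the
  package's own feature code so the map is exactly expressible by the
  feature set; BH_high = BH_low + Δ_true + N(0, σ²) with σ = 2 kcal/mol by
  default. Consequently the asymptotic MAE floor of any regressor is
  σ·√(2/π) ≈ 1.596 kcal/mol — the key parameter-recovery yardstick. A
  `hidden_driver` mode adds a latent component no feature encodes, for
  studying graceful degradation.
- Curation planting: exact counts round(fraction·n) of records get a
  failed TS flag, a rewired endpoint (spectrally distinct from both
  reactant and product), or a freshly re-embedded conformer of the correct
  isomer; clean records carry exact copies, so the per-reason summary must
  reproduce the plan exactly.

What passing on this generator does **not** show about real data: the
correction there is not exactly linear in five descriptors, descriptor
noise is correlated with structure, low-level failures are not independent
of chemistry, and conformer mismatches are subtler than fresh re-embeds.
The synthetic results validate the machinery (descriptors, bookkeeping,
training, attribution, thermochemistry) and the recoverability of a known
signal, not chemical accuracy.

## Problem sizes and numerical choices

Reference runs use n = 2,000 reactions for parameter recovery (train
1,700 with a GP subsample of 1,000), 1,000 records for curation, 5 × 600
for the baseline comparison, and 100/400/1600 × 3 repeats for learning
curves; the pipeline determinism check uses 500. Tolerances: descriptor
oracles 1e−8; connectivity 1e−4; conformation 1e−3; attribution additivity
1e−6 (achieved at ~1e−14); Gibbs oracle agreement 1e−6 kcal/mol.
Degenerate inputs are errors, not silent results: zero-variance targets,
non-finite features, TSs without exactly one imaginary mode, negative
frequencies in thermal sums.

## Known limitations

Eigenvalue comparison cannot separate cospectral graphs or enantiomers.
The e^−BH proxy is not a physical rate (no temperature in the exponent).
Positional atom mapping presumes IRC-connected records. The GP's linear
kernel component underestimates extrapolation variance relative to a
purely stationary kernel. The multitask head is not bit-reproducible
across BLAS builds (tree/GP heads are). Element coverage is H/C/N/O only.
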