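# Methods

## Scope and model

`koffgrid` regresses y = −log₁₀(k_off) (k_off in s⁻¹) on 3D-grid
interaction-field descriptors of the free ligand. The base-10 logarithm is
used because measured dissociation rates in the target applications span
three to five orders of magnitude. The approach assumes that dissociation
kinetics correlate with ligand surface properties — size, hydrophobic and
hydrophilic interaction capacity, their spatial balance — without any
receptor information; that is both its value (fast, structure-free) and its
fundamental limitation (no binding-site specificity).

## Ligand preparation

Structures are read with RDKit (SDF V2000, MOL2, SMILES one-per-line with
optional tab-separated ids). SMILES inputs are hydrogen-added and embedded
into a single ETKDGv3 conformer with a fixed seed: determinism was
preferred over conformer-ensemble averaging, and the downstream descriptors
are volume-like quantities that are tolerant of modest conformer noise.
Every molecule is then MMFF94-charged and MMFF94-minimized (max 5000
iterations, force tolerance 0.05 kcal·mol⁻¹·Å⁻¹, 8 Å non-bonded cutoff).
Non-convergence is a warning; an atom MMFF94 cannot type aborts only that
molecule. Protonation states are taken as drawn; no tautomer or charge-state
enumeration is attempted.

H-bond typing is heuristic: O with attached H → donor+acceptor, bare O →
acceptor, N with H → donor, bare neutral N → acceptor, everything else
inert. This gates the H-bond energy term only; it does not affect LJ or
electrostatics.

## Field energy function

Commercial grid-field software does not publish its force field, so the
energy function here is the package's own, chosen to be open, simple and
testable:

    E(r) = 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]
         + 332.06·q_i·q_p/(4r·r)
         + s_hb·[2(r₀/r)⁶ − 3(r₀/r)⁴]   (complementary donor/acceptor pairs only)

- 12-6 Lennard-Jones with Lorentz–Berthelot mixing against a per-element
  atom table (UFF-derived ε, σ; `data/probes.yaml`).
- Coulomb with the distance-dependent dielectric ε(r) = 4r, the standard
  implicit-screening choice for vacuum grids; 332.06 converts e²/Å to
  kcal/mol.
- A radial 6-4 H-bond well of depth s_hb at r₀ = 2.9 Å, applied only when
  probe and atom roles are complementary. No angular factor: descriptors
  integrate over volumes, where the angular modulation mostly averages out,
  and omitting it keeps the function closed-form testable.
- 8 Å cutoff (reused from the minimization setting); r clamped at 0.1 Å so
  lattice points inside atoms stay finite.

Truncation vs shifting: the default is plain truncation, which keeps the
closed-form landmarks exact (E(σ) = 0, E(2^{1/6}σ) = −ε, hand-computable
Coulomb values); the jump at 8 Å is a few 10⁻³ kcal/mol for realistic
parameters and irrelevant at the descriptor energy levels (≥ 0.2 kcal/mol
in magnitude). A `shift=True` option subtracts each pair's cutoff energy
for users who want a continuous field.

Probe parameters (charge, LJ, H-bond strength) ship as an editable YAML
table. DRY is uncharged and non-H-bonding (dispersion only); BOTH is defined
as the pointwise minimum of the OH2 and DRY fields; charged probes (N3+,
O−) have the deepest H-bond wells. These defaults are documented
conventions, not fitted constants.

## Lattice and voxel operations

Point-centered lattice, 0.5 Å spacing, 5 Å margin beyond the bounding box;
per axis dims = floor((extent + 2·margin)/spacing) + 1. Sublevel sets use
strict inequality (E < level); connected components use 26-connectivity
(scipy.ndimage); local minima are points strictly below all existing
neighbors with E < 0. All ties break lexicographically on (i, j, k), so
every operation is deterministic. Voxel volume is spacing³; surfaces count
exposed voxel faces × spacing². Volumes are therefore discretized: rigid
rotations move them by up to a voxel shell, which the tests bound
explicitly.

## Descriptor catalog

166 named slots over the nine probes:

| block | contents | count |
|---|---|---|
| OH2 | V, S, W1–8, IW1–8, CW1–8 (capacity W_k/S), Emin1–3, D12/D13/D23, BV11/BV21/BV12/BV22 | 36 |
| DRY | D1–8, ID1–8, Emin1–3, D12/D13/D23, BV×4 | 26 |
| O, O::, N1, N:=, N3+, O− | W1–8, Emin1–3, D12/D13/D23 each | 84 |
| BOTH | W1–8, Emin1–3, D12/D13/D23 | 14 |
| globals | POL, A, MW, RUG (S/V), GLOB, DIAM | 6 |

Ladders: W at −0.2, −0.5, −1.0, −2.0, −3.0, −4.0, −5.0, −6.0 kcal/mol;
D (DRY) at −0.2 … −1.6 in 0.2 steps. Best volumes are the largest and
second-largest connected-component volumes at −1.0 and −3.0 kcal/mol; BV
names are read rank-first (BV21 = rank-2 component at level 1 = −1.0).
D12/D13/D23 are distances between the three deepest minima ("D13-DRY" is a
minima-pair distance, not a 13th ladder slot). The molecular core for V and
S is the repulsive region of the water field (E ≥ +0.2 kcal/mol). POL is the
sum of per-element additive polarizability contributions
(`data/polarizability.yaml`, Miller-style values). Unsuffixed W-names
resolve to the water probe by convention. Absent features (fewer than three
minima, empty levels) are encoded as 0 so regression never sees missing
values; a failing descriptor poisons only its own slot.

The manifest is generated deterministically in code
(`descriptors.build_manifest`) and can be exported to YAML for inspection;
keeping one authoritative source avoids code/data drift.

## Stepwise selection and PLS

SMR: classic forward-entry/backward-removal stepwise OLS on standardized
training data — enter the candidate with the smallest partial-F p-value if
< 0.05, then drop any included variable whose coefficient p-value exceeds
0.10; stop when neither applies or `max_vars` is reached. Entry order is
preserved and defines the nested model sequence. With 166 candidate columns
a pure-noise response will still admit chance correlates at p < 0.05, so a
cap (default 9, matching the size of reported model tables) and the
parsimony rule below do the real complexity control. Near-constant columns
(sd ≤ 1e-12 relative) are excluded with a warning.

PLS1 is fit by NIPALS on autoscaled X (mean-centered, unit variance — the
chemometrics default; the scaling state is stored in the model so
predictions are exactly reproducible) and centered y, with y-deflation.
ncomp is validated against the rank of the scaled X; at full rank PLS
reproduces the OLS solution, which the tests exploit as an oracle
(alongside scikit-learn's PLSRegression as an independent cross-check).

Q² = 1 − PRESS/SS_tot over held-out predictions; every fold refits scaling
and PLS on its own training part; folds come from a seeded shuffle (LOO is
deterministic); SS_tot uses the full training-set mean. Metrics: RMSE,
MAPE = mean |(ŷ−y)/y| (undefined at y = 0), and the through-origin slope
b = Σy·ŷ/Σŷ² of observed on predicted (the direction is configurable in
principle; observed-on-predicted is the reported convention).

Model choice across the nested sequence: per subset, the component count
(grid 1–3 by default, reflecting that such models typically need only 1–2
latent variables) with the best Q²; across subsets, the smallest model whose
Q² is within `parsimony_tol` (default 0.05) of the maximum. "Complexity and
interpretability" is not an algorithm, so the tolerance is an explicit,
documented knob.

## Validation battery

- **Repeated splits** (default 1000): fresh seeded train/validation
  partitions at the configured fraction (defaults mirror 35/17-style
  ratios), refit of the *fixed* variable set, R² and R²_val recorded with
  sample sd (ddof = 1). A `reselect=True` flag re-runs SMR inside each
  repetition for a stricter assessment.
- **Y-permutation** (default 500): row 0 is the identity (reproducing the
  unpermuted R²/Q²), then seeded shuffles of y; the table holds
  |corr(y_perm, y)|, R², Q², supporting the permutation scatter plot and
  regression intercepts. A real model shows R²/Q² dropping sharply as the
  correlation falls.
- **External test**: predictions on an id-disjoint set (overlap is an
  error), reporting R²_test, RMSEP and the through-origin slope.

## Synthetic data

Three generator tiers stand in for the proprietary ligand/kinetics sets,
which users supply at run time:

- **Toy molecules** (single LJ sphere, ±q dipole, symmetric tetrahedron,
  donor/acceptor pair) give closed-form or by-construction field values.
- **Ligand series**: para-substituted N-methylbenzamides (amide head =
  donor+acceptor, tunable polar/apolar tail), embedded and MMFF-prepared
  deterministically per seed. Five such ligands drive the end-to-end CLI
  tests. Synthetic k_off values for them are a linear surrogate in
  heavy-atom count with seeded noise — no kinetic realism claimed or needed
  for pipeline testing.
- **Planted tables**: 166 manifest-named Gaussian columns with exchangeable
  correlation ρ and y = Xβ + N(0, σ²). Defaults (n = 60, two true
  variables, β = (2, −1), σ = 0.3, ρ = 0.3) produce a clear but noisy
  signal comparable in difficulty to a well-behaved 2-descriptor QSKR.
  Random streams are namespaced per generator, so adding a fixture never
  shifts another's output.

Passing on these fixtures demonstrates algorithmic correctness (oracle
equivalence, invariants, recovery of a known signal under noise and
collinearity) — not predictive accuracy on real kinetics data, which
depends on measured k_off tables the package's users provide.

## Problem sizes and numerical choices

Test and acceptance runs use 5-ligand series, ~40³ lattices for field
oracle checks, 60×166 planted tables, 100-replicate recovery studies,
100-permutation scrambling and 10–100-rep split studies — sizes chosen so
the full pipeline exercises every code path in minutes while the statistics
remain stable. Production-scale settings (1000 splits, 500 permutations)
are the shipped defaults of the validation API and CLI.

Degenerate inputs are handled explicitly: 1-row or constant-response
validation splits yield NaN R²_val rather than division errors; empty
sublevel sets yield 0-valued descriptors; all-zero prediction vectors make
the through-origin slope an error. CSVs are re-read with round-trip float
parsing so resume/rewrite cycles are byte-stable.

## Known limitations

- The energy function is a documented open surrogate, not the commercial
  grid force field; descriptor *values* are not interchangeable with
  commercial output, though the descriptor semantics match.
- No angular H-bond term, no polarization, no conformer ensembles, no
  tautomer/protonation enumeration.
- Ligand-only: the model cannot distinguish targets; one model per
  receptor dataset.
- Stepwise selection on wide tables is greedy and can admit chance
  correlates; the validation battery, not the selection p-values, is the
  evidence of model quality.
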