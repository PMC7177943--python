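# koffgrid

Grid-based molecular-interaction-field (MIF) descriptors and PLS regression
for predicting ligand **dissociation rate constants** (k_off).

## The problem

How long a drug stays bound to its target — the residence time τ = 1/k_off —
is often a better predictor of efficacy than equilibrium affinity, but
measuring k_off is slow and expensive, and simulation-based estimates
(random-acceleration or steered MD) need the receptor structure and heavy
compute. For several targets (HSP90α, adenosine A1 receptor, p38 MAPK),
ligand-only 3D surface descriptors have been shown to carry enough signal to
regress −log₁₀(k_off) with just two or three variables. `koffgrid`
implements that pipeline end to end for computational chemists: structures
in, calibrated k_off predictions out, with the full validation battery
needed to trust a QSKR (quantitative structure–kinetics relationship) model.

## The method

1. **Preparation.** Ligands (SDF/MOL2/SMILES) get MMFF94 partial charges and
   a conjugate-gradient MMFF94 minimization (5000 steps max, gradient
   tolerance 0.05 kcal·mol⁻¹·Å⁻¹, 8 Å non-bonded cutoff).
2. **Fields.** Nine probes — water (OH2), hydrophobic (DRY), carbonyl O,
   amphipathic (BOTH), carboxy O::, amide N1, sp² N:=, cationic N3+, anionic
   O⁻ — are evaluated on a 0.5 Å lattice with a 5 Å margin:

       E(r) = 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]
            + 332.06·q_i·q_probe/(4r·r)                (ε(r) = 4r)
            + s_hb[2(r₀/r)⁶ − 3(r₀/r)⁴]                (donor↔acceptor only)

   with Lorentz–Berthelot mixing, an 8 Å cutoff and a 0.1 Å distance clamp.
   BOTH is the pointwise minimum of the OH2 and DRY fields.
3. **Descriptors.** Each field is reduced to named quantities — sublevel-set
   volumes on energy ladders (W1–W8, D1–D8), integy moments (IW/ID),
   capacity factors, the three deepest local minima and their pairwise
   distances (Emin1–3, D12/D13/D23), best (largest-component) volumes at
   −1.0/−3.0 kcal/mol (BV11/BV21/BV12/BV22), molecular volume and surface
   (V, S), amphiphilic moment A, additive polarizability POL and a few
   globals — 166 slots per molecule.
4. **Modeling.** Stepwise multiple regression (entry p < 0.05, removal
   p > 0.10) orders the variables; PLS1 (NIPALS, autoscaled X, centered y)
   fits each nested subset: X = TPᵀ + E, Y = UCᵀ + G, Y = TCᵀ + F. The
   target is y = −log₁₀(k_off).
5. **Validation.** Cross-validated Q² = 1 − PRESS/SS_tot (3-fold, 5-fold or
   LOO), RMSE and MAPE, through-origin slope of observed vs predicted,
   repeated random-split distributions of R²/R²_val, Y-permutation
   (scrambled-response) testing, and guarded external-test evaluation.

## Worked example

`examples/03_train_and_validate.py` plants a 60 × 166 descriptor table in
which only `W3-N3+` and `D8-DRY` carry signal (y = 2·x₁ − x₂ + ε, σ = 0.3),
then runs the full selection/validation stack:

```
stepwise entry order: ['W3-N3+', 'D8-DRY', 'W4-O', 'W6-O-'] ...
chosen model: W3-N3++D8-DRY with 2 component(s)
  R2=0.985  Q2=0.982  RMSE=0.327  R2_val=0.964  slope=1.0000
100 repeated splits: R2 = 0.98 +/- 0.01, R2_val = 0.97 +/- 0.02
Y-permutation: unpermuted R2 = 0.982, mean scrambled R2 = 0.029
```

Stepwise regression recovers exactly the planted pair; the parsimony rule
keeps the two-variable model; validation R² tracks training R² across 100
random splits; and scrambling the response collapses R² to noise — the
signature of a model that is not a chance correlation.

The other examples show the field engine on a toy dipole
(`01_interaction_fields.py`), a full descriptor vector for aspirin
(`02_descriptors.py`), and the shell pipeline
(`04_cli_pipeline.sh`) — `koffgrid describe/train/validate/predict` on a
generated five-ligand benzamide series, ending with per-molecule predicted
k_off values in s⁻¹.

## Command-line interface

```bash
koffgrid describe --structures ligands.sdf --output-dir out
koffgrid train    --descriptors out/descriptors.csv --kinetics koff.csv \
                  --output-dir out --seed 11
koffgrid validate --model out/model.json --descriptors out/descriptors.csv \
                  --kinetics koff.csv --output-dir out
koffgrid predict  --model out/model.json --structures new_ligands.sdf \
                  --output-dir out
```

The kinetics CSV has columns `molecule_id,k_off` (k_off in s⁻¹). All
settings can live in a YAML config (`--config`); CLI flags override it.
Every output directory carries a `provenance.json`, and two runs with the
same inputs, config and seed are byte-identical.

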