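#!/usr/bin/env bash
# Full shell pipeline on generated fixtures: prep -> describe -> train ->
# validate -> predict.  Run from anywhere; writes into ./koffgrid_demo.
set -euo pipefail
mkdir -p koffgrid_demo && cd koffgrid_demo

python - <<'PY'
import koffgrid as kg
from koffgrid.fixtures import make_series_kinetics, write_series_sdf
mols = kg.make_ligand_series(5, seed=3)
write_series_sdf(mols, "series.sdf")
make_series_kinetics(mols, seed=3).to_csv("kinetics.csv", index=False)
PY

cat > cfg.yaml <<'YAML'
cv_scheme: LOO          # leave-one-out: the series is small
train_fraction: 0.8
max_vars: 2
ncomp_grid: [1, 2]
YAML

koffgrid describe --config cfg.yaml --structures series.sdf --output-dir out --seed 11
koffgrid train    --config cfg.yaml --descriptors out/descriptors.csv \
                  --kinetics kinetics.csv --output-dir out --seed 11
koffgrid validate --config cfg.yaml --model out/model.json \
                  --descriptors out/descriptors.csv --kinetics kinetics.csv \
                  --n-reps 50 --n-perms 50 --output-dir out --seed 11
koffgrid predict  --config cfg.yaml --model out/model.json \
                  --structures series.sdf --output-dir out --seed 11

echo "predicted k_off values:"
cat out/predictions.csv
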