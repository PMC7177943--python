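"""Robustness battery: repeated random-split modeling, Y-permutation and
external-test evaluation.

A model that survives this battery has (i) stable R^2/R2_val distributions
over many random train/validation splits, (ii) R^2 and Q^2 that collapse
when the response is scrambled (so the fit is not a chance correlation), and
(iii) acceptable accuracy on an independent test set disjoint from training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import (
    ModelingDataset,
    PLSModel,
    pls_fit,
    pls_predict,
    q2_cv,
    r_squared,
    rmse,
    smr_select,
    through_origin_slope,
)


@dataclass
class RepeatedSplitSummary:
    """Per-repetition (seed, R2, R2_val) plus sample mean +/- sd (ddof=1)."""

    table: pd.DataFrame
    r2_mean: float
    r2_sd: float
    r2_val_mean: float
    r2_val_sd: float


@dataclass
class ValidationReport:
    repeated: RepeatedSplitSummary | None = None
    permutation: pd.DataFrame | None = None
    external: dict = field(default_factory=dict)


def repeated_splits(
    data: ModelingDataset,
    variables: list[str],
    ncomp: int,
    n_reps: int = 1000,
    train_fraction: float = 35 / 52,
    seed: int = 0,
    reselect: bool = False,
) -> RepeatedSplitSummary:
    """Refit the fixed-variable PLS model over many seeded random splits.

    Each repetition draws a fresh train/validation partition of all rows at
    ``train_fraction`` and records the training R^2 and validation R^2.  By
    default the variable set stays fixed (the usual practice when stress-
    testing one chosen model); ``reselect=True`` re-runs stepwise selection
    inside every repetition for a fully honest, slower, assessment.
    Degenerate repetitions are recorded with NaN metrics.
    """
    n = len(data.X)
    n_train = int(round(train_fraction * n))
    if n_train < ncomp + 2 or n - n_train < 1:
        raise ValueError(
            f"train_fraction={train_fraction} leaves too few rows (n={n})"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        order = np.random.default_rng(rep_seed).permutation(n)
        labels = np.array(["validation"] * n, dtype=object)
        labels[order[:n_train]] = "train"
        sub = ModelingDataset(data.X, data.y, pd.Series(labels, index=data.X.index))
        try:
            rep_vars = smr_select(sub) if reselect else variables
            if not rep_vars:
                raise ValueError("reselection chose no variables")
            model = pls_fit(sub, rep_vars, min(ncomp, len(rep_vars)))
            Xtr, ytr = sub.rows("train")
            Xval, yval = sub.rows("validation")
            r2 = r_squared(pls_predict(model, Xtr), ytr.to_numpy())
            yval_np = yval.to_numpy()
            r2_val = (
                r_squared(pls_predict(model, Xval), yval_np)
                if np.ptp(yval_np) > 0 else np.nan
            )
        except (ValueError, KeyError):
            r2 = r2_val = np.nan
        rows.append({"seed": rep_seed, "R2": r2, "R2_val": r2_val})
    table = pd.DataFrame(rows)

    def _stats(col: str) -> tuple[float, float]:
        ok = table[col].dropna()
        if len(ok) == 0:
            return float("nan"), float("nan")
        return float(ok.mean()), float(ok.std(ddof=1)) if len(ok) > 1 else 0.0

    r2_mean, r2_sd = _stats("R2")
    r2_val_mean, r2_val_sd = _stats("R2_val")
    return RepeatedSplitSummary(
        table=table, r2_mean=r2_mean, r2_sd=r2_sd,
        r2_val_mean=r2_val_mean, r2_val_sd=r2_val_sd,
    )


def y_permutation(
    data: ModelingDataset,
    variables: list[str],
    ncomp: int,
    n_perms: int = 500,
    scheme: str = "5-fold",
    seed: int = 0,
) -> pd.DataFrame:
    """Y-scrambling table: (|corr(y_perm, y)|, R2, Q2) per permutation.

    Row 0 is the identity permutation and reproduces the unpermuted R^2 and
    Q^2; subsequent rows shuffle y with a seeded generator and refit on the
    training split.  Supports the scatter of R^2/Q^2 against the
    permutation-original correlation and its fitted intercepts.
    """
    if len(data.X) < 4:
        raise ValueError("y-permutation needs at least 4 samples")
    rng = np.random.default_rng(seed)
    Xtr, ytr = data.rows("train")
    y_orig = ytr.to_numpy(dtype=float)
    rows = []
    for rep in range(n_perms + 1):
        if rep == 0:
            y_perm = y_orig.copy()
        else:
            y_perm = y_orig[rng.permutation(len(y_orig))]
        corr = abs(float(np.corrcoef(y_perm, y_orig)[0, 1]))
        sub = ModelingDataset(
            Xtr, pd.Series(y_perm, index=Xtr.index),
            pd.Series("train", index=Xtr.index),
        )
        try:
            model = pls_fit(sub, variables, ncomp)
            r2 = r_squared(pls_predict(model, Xtr), y_perm)
            q2 = q2_cv(sub, variables, ncomp, scheme=scheme, seed=seed)
        except ValueError:
            r2 = q2 = np.nan
        rows.append({"perm": rep, "abs_corr": corr, "R2": r2, "Q2": q2})
    return pd.DataFrame(rows)


def permutation_intercepts(table: pd.DataFrame) -> dict[str, float]:
    """Intercepts of R^2 and Q^2 regressed on |corr(y_perm, y)|."""
    out = {}
    for col in ("R2", "Q2"):
        ok = table.dropna(subset=[col])
        slope, intercept = np.polyfit(ok["abs_corr"], ok[col], 1)
        out[f"{col}_intercept"] = float(intercept)
        out[f"{col}_slope"] = float(slope)
    return out


def evaluate_external(
    model: PLSModel,
    test: ModelingDataset,
    training_ids: list[str] | None = None,
) -> dict[str, float]:
    """Predict an independent test set and report (R2_test, RMSEP, slope).

    The test ids must be disjoint from the training ids; any overlap is an
    error listing the offenders.
    """
    if training_ids is not None:
        overlap = sorted(set(map(str, test.X.index)) & set(map(str, training_ids)))
        if overlap:
            raise ValueError(f"test set overlaps training ids: {overlap}")
    pred = pls_predict(model, test.X).to_numpy()
    y = test.y.to_numpy(dtype=float)
    return {
        "R2_test": r_squared(pred, y),
        "RMSEP": rmse(pred, y),
        "slope": through_origin_slope(y, pred),
    }
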