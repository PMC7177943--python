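"""Stepwise variable selection and PLS regression to -log10(k_off).

The regression engine is PLS1 fit by NIPALS on autoscaled (mean-centered,
unit-variance) predictors and a centered response:

    X = T P' + E        Y = U C' + G        Y = T C' + F

Variable subsets come from classic stepwise multiple regression (SMR):
forward entry by smallest partial-F p-value (< p_enter), backward removal of
any included variable whose p-value exceeds p_remove.  Model quality is
reported as R^2, cross-validated Q^2 (3-fold, 5-fold or leave-one-out),
RMSE, MAPE, validation-set R^2/RMSEP and the slope of the through-origin
regression of observed on predicted.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ModelingDataset:
    """Descriptor matrix, targets and split labels, aligned on molecule id."""

    X: pd.DataFrame
    y: pd.Series
    split: pd.Series  # train | validation | test per row

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share an index")
        if not self.X.index.equals(self.split.index):
            raise ValueError("X and split must share an index")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("dataset must not contain missing values")
        if self.X.columns.duplicated().any():
            raise ValueError("descriptor column names must be unique")
        if len(self.X) < 3:
            raise ValueError("need at least 3 samples")
        bad = set(self.split) - {"train", "validation", "test"}
        if bad:
            raise ValueError(f"unknown split labels: {sorted(bad)}")

    @property
    def train(self) -> "ModelingDataset":
        m = self.split == "train"
        return ModelingDataset(self.X[m], self.y[m], self.split[m])

    def rows(self, label: str) -> tuple[pd.DataFrame, pd.Series]:
        m = self.split == label
        return self.X[m], self.y[m]

    @classmethod
    def from_arrays(cls, X, y, split=None, columns=None, index=None) -> "ModelingDataset":
        Xdf = pd.DataFrame(np.asarray(X, dtype=float), columns=columns, index=index)
        Xdf.columns = [str(c) for c in Xdf.columns]
        ys = pd.Series(np.asarray(y, dtype=float), index=Xdf.index)
        if split is None:
            split = pd.Series("train", index=Xdf.index)
        else:
            split = pd.Series(split, index=Xdf.index)
        return cls(Xdf, ys, split)


def random_split(
    index: pd.Index, n_train: int, seed: int
) -> pd.Series:
    """Seeded train/validation split labels over an index."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(index))
    labels = np.array(["validation"] * len(index), dtype=object)
    labels[order[:n_train]] = "train"
    return pd.Series(labels, index=index)


# ---------------------------------------------------------------------------
# stepwise multiple regression
# ---------------------------------------------------------------------------

def _ols_pvalues(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for the non-intercept coefficients of OLS."""
    n, k = Z.shape
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    dof = n - k
    if dof <= 0:
        return np.full(k - 1, np.nan)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t[1:]), dof)


def smr_select(
    data: ModelingDataset,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_vars: int | None = None,
) -> list[str]:
    """Stepwise OLS variable selection on standardized training data.

    Returns selected variable names in entry order.  Constant training
    columns are excluded with a warning; partial-F entry tests and
    coefficient-t removal tests are equivalent for single-variable moves.
    """
    Xtr, ytr = data.rows("train")
    n = len(Xtr)
    if n < 4:
        raise ValueError(f"too few training rows ({n}) for stepwise selection")
    std = Xtr.std(ddof=1)
    # relative tolerance: a column constant up to rounding carries no signal
    tiny = std <= 1e-12 * Xtr.abs().mean().clip(lower=1.0)
    constant = std[tiny].index.tolist()
    if constant:
        warnings.warn(f"excluding constant columns: {constant[:5]}"
                      + ("..." if len(constant) > 5 else ""))
    usable = [c for c in Xtr.columns if c not in constant]
    Xs = ((Xtr[usable] - Xtr[usable].mean()) / std[usable]).to_numpy()
    y = (ytr - ytr.mean()).to_numpy()
    col_index = {c: i for i, c in enumerate(usable)}

    selected: list[str] = []
    max_vars = max_vars if max_vars is not None else len(usable)

    steps = 0
    while True:
        steps += 1
        if steps > 2 * len(usable) + 10:  # cycling guard for pathological collinearity
            logger.warning("SMR stopped by step cap")
            break
        k = len(selected)
        if k >= max_vars or n < k + 3:
            break
        # forward step: partial F of each candidate given the current model
        Z = np.column_stack([np.ones(n)] + [Xs[:, col_index[c]] for c in selected])
        Q, _ = np.linalg.qr(Z)
        ry = y - Q @ (Q.T @ y)
        sse0 = float(ry @ ry)
        candidates = [c for c in usable if c not in selected]
        if not candidates or sse0 <= 1e-12:
            break
        Xc = Xs[:, [col_index[c] for c in candidates]]
        Rc = Xc - Q @ (Q.T @ Xc)
        rnorm2 = (Rc * Rc).sum(axis=0)
        valid = rnorm2 > 1e-10
        num = np.zeros(len(candidates))
        num[valid] = (ry @ Rc[:, valid]) ** 2 / rnorm2[valid]
        dof = n - k - 2
        sse1 = np.maximum(sse0 - num, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(valid, num / (sse1 / dof), 0.0)
        pvals = stats.f.sf(F, 1, dof)
        best = int(np.argmin(np.where(valid, pvals, np.inf)))
        entered = False
        if valid[best] and pvals[best] < p_enter:
            selected.append(candidates[best])
            entered = True

        # backward step: drop the worst included variable above p_remove
        removed = True
        while removed and len(selected) > 1:
            removed = False
            Zf = np.column_stack(
                [np.ones(n)] + [Xs[:, col_index[c]] for c in selected]
            )
            p_sel = _ols_pvalues(Zf, y)
            worst = int(np.argmax(p_sel))
            if np.isfinite(p_sel[worst]) and p_sel[worst] > p_remove:
                dropped = selected.pop(worst)
                logger.info("SMR removed %s (p=%.3g)", dropped, p_sel[worst])
                removed = True

        if not entered:
            break
    return selected


# ---------------------------------------------------------------------------
# PLS (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted PLS1 model with its scaling state and factor matrices."""

    var_names: list[str]
    ncomp: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    W: np.ndarray  # (p, a) X weights
    P: np.ndarray  # (p, a) X loadings
    C: np.ndarray  # (a,)   Y weights
    T: np.ndarray  # (n, a) X scores
    U: np.ndarray  # (n, a) Y scores
    E: np.ndarray = dc_field(repr=False, default=None)  # X residuals
    F: np.ndarray = dc_field(repr=False, default=None)  # Y residuals (X-score form)
    G: np.ndarray = dc_field(repr=False, default=None)  # Y residuals (Y-score form)
    coef_: np.ndarray = None  # regression vector in original units
    intercept_: float = 0.0

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        return pls_predict(self, X_new)

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "var_names": self.var_names,
            "ncomp": self.ncomp,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "C": self.C.tolist(),
            "T": self.T.tolist(),
            "U": self.U.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }
        if extra:
            doc["provenance"] = extra
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            var_names=list(doc["var_names"]),
            ncomp=int(doc["ncomp"]),
            x_mean=np.asarray(doc["x_mean"]),
            x_scale=np.asarray(doc["x_scale"]),
            y_mean=float(doc["y_mean"]),
            W=np.asarray(doc["W"]),
            P=np.asarray(doc["P"]),
            C=np.asarray(doc["C"]),
            T=np.asarray(doc["T"]),
            U=np.asarray(doc["U"]),
            coef_=np.asarray(doc["coef"]),
            intercept_=float(doc["intercept"]),
        )


def pls_fit(data: ModelingDataset, variables: list[str], ncomp: int) -> PLSModel:
    """NIPALS PLS1 on the training rows, autoscaled X and centered y."""
    if ncomp < 1:
        raise ValueError("ncomp must be >= 1")
    missing = [v for v in variables if v not in data.X.columns]
    if missing:
        raise KeyError(f"variables not in dataset: {missing}")
    Xtr, ytr = data.rows("train")
    X = Xtr[list(variables)].to_numpy(dtype=float)
    y = ytr.to_numpy(dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    if np.any(x_scale == 0):
        bad = [variables[i] for i in np.where(x_scale == 0)[0]]
        raise ValueError(f"zero-variance selected columns: {bad}")
    Xs = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    rank = np.linalg.matrix_rank(Xs)
    if ncomp > rank:
        raise ValueError(f"ncomp={ncomp} exceeds rank {rank} of the scaled X")

    Xa, ya = Xs.copy(), yc.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    C = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    U = np.zeros((n, ncomp))
    for a in range(ncomp):
        w = Xa.T @ ya
        wnorm = np.linalg.norm(w)
        if wnorm < 1e-14:
            raise ValueError(f"NIPALS degenerated at component {a + 1}")
        w /= wnorm
        t = Xa @ w
        tt = float(t @ t)
        c = float(t @ ya) / tt
        p_load = Xa.T @ t / tt
        u = ya * c / (c * c) if c != 0 else np.zeros(n)
        W[:, a], P[:, a], C[a], T[:, a], U[:, a] = w, p_load, c, t, u
        Xa = Xa - np.outer(t, p_load)
        ya = ya - t * c

    # regression vector in scaled then original units
    B = W @ np.linalg.solve(P.T @ W, C)
    coef = B / x_scale
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        var_names=list(variables), ncomp=ncomp, x_mean=x_mean, x_scale=x_scale,
        y_mean=y_mean, W=W, P=P, C=C, T=T, U=U, E=Xa, F=ya, G=ya,
        coef_=coef, intercept_=intercept,
    )


def pls_predict(model: PLSModel, X_new: pd.DataFrame) -> pd.Series:
    """Predict y for new rows; raises KeyError naming any missing column."""
    missing = [v for v in model.var_names if v not in X_new.columns]
    if missing:
        raise KeyError(f"missing descriptor columns: {missing}")
    X = X_new[model.var_names].to_numpy(dtype=float)
    yhat = X @ model.coef_ + model.intercept_
    return pd.Series(yhat, index=X_new.index)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y_pred, y_obs) -> float:
    """Root-mean-square error."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if y_pred.shape != y_obs.shape or y_pred.size < 1:
        raise ValueError("rmse needs equal-length non-empty arrays")
    return float(np.sqrt(np.mean((y_pred - y_obs) ** 2)))


def mape(y_pred, y_obs) -> float:
    """Mean absolute percentage error, mean |(yhat - y)/y|."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if y_pred.shape != y_obs.shape or y_pred.size < 1:
        raise ValueError("mape needs equal-length non-empty arrays")
    if np.any(y_obs == 0):
        raise ValueError("mape undefined when an observed value is 0")
    return float(np.mean(np.abs((y_pred - y_obs) / y_obs)))


def r_squared(y_pred, y_obs) -> float:
    y_pred = np.asarray(y_pred, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    ss_res = float(((y_obs - y_pred) ** 2).sum())
    ss_tot = float(((y_obs - y_obs.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def through_origin_slope(y_obs, y_pred) -> float:
    """Least-squares slope b of the through-origin fit y_obs = b * y_pred."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    denom = float(y_pred @ y_pred)
    if denom <= 0:
        raise ValueError("through-origin slope undefined for all-zero predictions")
    return float(y_obs @ y_pred) / denom


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

_SCHEMES = {"3-fold": 3, "5-fold": 5, "loo": None, "LOO": None}


def _folds(n: int, scheme: str, seed: int) -> list[np.ndarray]:
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown CV scheme {scheme!r}; use 3-fold, 5-fold or LOO")
    k = _SCHEMES[scheme]
    if k is None:
        return [np.array([i]) for i in range(n)]
    if n < k * 2:
        raise ValueError(f"{scheme} CV needs at least {2 * k} samples, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    return [order[i::k] for i in range(k)]


def q2_cv(
    data: ModelingDataset,
    variables: list[str],
    ncomp: int,
    scheme: str = "5-fold",
    seed: int = 0,
) -> float:
    """Cross-validated Q^2 = 1 - PRESS/SS_tot over held-out predictions.

    Each fold refits scaling and PLS on its own training part; LOO is
    deterministic, k-fold folds come from a seeded shuffle.  SS_tot uses the
    full training-set mean.
    """
    Xtr, ytr = data.rows("train")
    X = Xtr[list(variables)]
    y = ytr.to_numpy(dtype=float)
    n = len(X)
    press = 0.0
    for heldout in _folds(n, scheme, seed):
        train_mask = np.ones(n, dtype=bool)
        train_mask[heldout] = False
        if train_mask.sum() < 2:
            raise ValueError("CV fold leaves fewer than 2 training samples")
        sub = ModelingDataset.from_arrays(
            X.iloc[train_mask].to_numpy(), y[train_mask],
            columns=list(variables), index=X.index[train_mask],
        )
        model = pls_fit(sub, list(variables), ncomp)
        pred = pls_predict(model, X.iloc[heldout]).to_numpy()
        press += float(((y[heldout] - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


# ---------------------------------------------------------------------------
# nested model selection
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Summary metrics of one fitted PLS model."""

    n_vars: int
    variables: list[str]
    ncomp: int
    r2: float
    q2: float
    cv_scheme: str
    rmse: float
    mape: float
    r2_val: float
    rmsep: float
    slope: float

    def as_row(self) -> dict:
        return {
            "n_vars": self.n_vars,
            "variables": "+".join(self.variables),
            "ncomp": self.ncomp,
            "R2": self.r2,
            "Q2": self.q2,
            "cv_scheme": self.cv_scheme,
            "RMSE": self.rmse,
            "MAPE": self.mape,
            "R2_val": self.r2_val,
            "RMSEP": self.rmsep,
            "slope": self.slope,
        }


@dataclass
class ModelSelection:
    model: PLSModel
    report: pd.DataFrame
    chosen: int  # row index into report


def fit_report(
    data: ModelingDataset,
    variables: list[str],
    ncomp: int,
    scheme: str = "5-fold",
    seed: int = 0,
) -> tuple[PLSModel, FitReport]:
    """Fit one PLS model and compute the full metric row."""
    model = pls_fit(data, variables, ncomp)
    Xtr, ytr = data.rows("train")
    pred_tr = pls_predict(model, Xtr).to_numpy()
    ytr_np = ytr.to_numpy(dtype=float)
    Xval, yval = data.rows("validation")
    if len(Xval):
        pred_val = pls_predict(model, Xval).to_numpy()
        yval_np = yval.to_numpy(dtype=float)
        # R^2 needs response variance; a 1-row or constant validation set has none
        r2_val = r_squared(pred_val, yval_np) if np.ptp(yval_np) > 0 else np.nan
        rmsep = rmse(pred_val, yval_np)
    else:
        r2_val, rmsep = np.nan, np.nan
    report = FitReport(
        n_vars=len(variables),
        variables=list(variables),
        ncomp=ncomp,
        r2=r_squared(pred_tr, ytr_np),
        q2=q2_cv(data, variables, ncomp, scheme=scheme, seed=seed),
        cv_scheme=scheme,
        rmse=rmse(pred_tr, ytr_np),
        mape=mape(pred_tr, ytr_np),
        r2_val=r2_val,
        rmsep=rmsep,
        slope=through_origin_slope(ytr_np, pred_tr),
    )
    return model, report


def select_model(
    data: ModelingDataset,
    variable_sequence: list[str],
    ncomp_grid: tuple[int, ...] = (1, 2, 3),
    scheme: str = "5-fold",
    seed: int = 0,
    parsimony_tol: float = 0.05,
) -> ModelSelection:
    """Fit the nested models 1..k of an entry-ordered variable sequence.

    For each nested subset, the component count is the grid value (capped at
    the subset size and rank) with the highest Q^2.  The flagged optimum is
    the smallest nested model whose Q^2 is within ``parsimony_tol`` of the
    best Q^2 — a configurable stand-in for choosing by complexity and
    interpretability.
    """
    if not variable_sequence:
        raise ValueError("need at least one candidate variable")
    rows = []
    models = []
    for k in range(1, len(variable_sequence) + 1):
        variables = variable_sequence[:k]
        best = None
        for ncomp in ncomp_grid:
            if ncomp > len(variables):
                continue
            try:
                model, rep = fit_report(data, variables, ncomp, scheme, seed)
            except ValueError:
                continue
            if best is None or rep.q2 > best[1].q2:
                best = (model, rep)
        if best is None:
            raise ValueError(f"no feasible component count for subset of size {k}")
        models.append(best[0])
        rows.append(best[1].as_row())
    report = pd.DataFrame(rows)
    q2 = report["Q2"].to_numpy()
    chosen = int(np.nonzero(q2 >= q2.max() - parsimony_tol)[0][0])
    report["selected"] = [i == chosen for i in range(len(rows))]
    return ModelSelection(model=models[chosen], report=report, chosen=chosen)
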