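"""Univariate probe screening and supervised principal-components tuning.

The selection principle: with probes standardized, score each probe by
the univariate OLS slope of the log2 uptake outcome on that probe (equal
to Pearson r times sd(y)), keep probes whose |slope| clears a threshold,
and pick the threshold together with the number of principal components
of the reduced matrix by k-fold cross-validation of held-out prediction
RMSE. Probes without a gene symbol are retained throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, standardize

__all__ = [
    "UnivariateScoreTable",
    "SupervisedPCChoice",
    "univariate_coefficients",
    "select_probes",
    "supervised_pc_cv",
]


@dataclass
class SupervisedPCChoice:
    """CV grid over (threshold, components) and the chosen pair."""

    grid: pd.DataFrame  # columns: threshold, n_components, cv_rmse
    threshold: float
    n_components: int


UnivariateScoreTable = pd.DataFrame  # columns: probe_id index, gene_symbol, beta, rank


def univariate_coefficients(Xstd: ExpressionMatrix, y) -> pd.DataFrame:
    """Per-probe univariate OLS slope of y on the (standardized) probe.

    Returns a table indexed by probe id with the slope ``beta``, the gene
    symbol (may be null) and the rank by |beta| (1 = strongest). For
    probes standardized on the same samples, beta equals corr(x, y) *
    sd(y); the general cov/var formula is used so the function is also
    correct inside cross-validation folds where rows are re-standardized
    on a subset.
    """
    y = np.asarray(y, dtype=float)
    V = Xstd.values.to_numpy()
    if V.shape[1] != len(y):
        raise ValueError(
            f"sample mismatch: matrix has {V.shape[1]} samples, y has {len(y)}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = len(y)
    xc = V - V.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = xc @ yc / sxx
    beta = np.where(sxx > 0, beta, 0.0)
    table = pd.DataFrame(
        {
            "gene_symbol": (
                Xstd.gene_symbols
                if Xstd.gene_symbols is not None
                else pd.Series(index=Xstd.probe_ids, dtype=object)
            ),
            "beta": beta,
        },
        index=Xstd.probe_ids,
    )
    table["rank"] = (-table["beta"].abs()).rank(method="first").astype(int)
    return table


def select_probes(table: pd.DataFrame, threshold: float) -> pd.Index:
    """Probes with |beta| >= threshold (inclusive).

    Unannotated probes are retained. Raises if the selection is empty.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sel = table.index[table["beta"].abs() >= threshold]
    if len(sel) == 0:
        raise ValueError(
            f"no probe passes |beta| >= {threshold}; max |beta| is "
            f"{table['beta'].abs().max():.4g} — lower the threshold"
        )
    return sel


def _pc_fit_predict(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, m: int
) -> np.ndarray:
    """Regress y on the first m principal components of Xtr; predict Xte.

    Component signs are fixed so each component's largest-magnitude
    loading is positive.
    """
    mu = Xtr.mean(axis=0)
    Xc = Xtr - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if m > rank:
        raise ValueError(f"{m} components requested but rank is {rank}")
    V = Vt[:m].T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(m)])
    V = V * flip
    T = Xc @ V
    coef, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(T)), T]), ytr, rcond=None
    )
    Tte = (Xte - mu) @ V
    return coef[0] + Tte @ coef[1:]


def supervised_pc_cv(
    Xstd: ExpressionMatrix,
    y,
    thresholds,
    max_components: int = 3,
    k: int = 10,
    seed: int = 0,
) -> SupervisedPCChoice:
    """Choose (|beta| threshold, principal components) by k-fold CV.

    Inside each training fold the probes are re-standardized and scored
    from that fold only (no leakage); held-out samples are projected onto
    the fold's components and the pooled held-out RMSE is reported per
    grid point. Ties are broken toward the larger threshold (fewer
    probes), then the smaller component count.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold grid")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    if min(len(f) for f in folds) < 1 or n - max(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 training samples")

    raw = Xstd.values
    sq_err = {
        (th, m): [] for th in thresholds for m in range(1, max_components + 1)
    }
    for fold in folds:
        tr = np.setdiff1d(np.arange(n), fold)
        Xtr_m = standardize(
            ExpressionMatrix(values=raw.iloc[:, tr], gene_symbols=Xstd.gene_symbols)
        )
        tab = univariate_coefficients(Xtr_m, y[tr])
        for th in thresholds:
            try:
                sel = select_probes(tab, th)
            except ValueError:
                for m in range(1, max_components + 1):
                    sq_err[(th, m)].append(None)
                continue
            Xtr = Xtr_m.values.loc[sel].to_numpy().T
            Xte_raw = raw.iloc[:, fold]
            p = Xtr_m.standardization_params.loc[sel]
            Xte = (
                Xte_raw.loc[sel].sub(p["mean"], axis=0).div(p["sd"], axis=0)
            ).to_numpy().T
            for m in range(1, max_components + 1):
                try:
                    pred = _pc_fit_predict(Xtr, y[tr], Xte, m)
                except ValueError:
                    sq_err[(th, m)].append(None)
                    continue
                sq_err[(th, m)].append(((y[fold] - pred) ** 2).tolist())

    rows = []
    for (th, m), chunks in sq_err.items():
        if any(ch is None for ch in chunks):
            rows.append({"threshold": th, "n_components": m, "cv_rmse": np.nan})
            continue
        errs = np.concatenate([np.asarray(ch) for ch in chunks])
        rows.append(
            {"threshold": th, "n_components": m, "cv_rmse": float(np.sqrt(errs.mean()))}
        )
    grid = pd.DataFrame(rows)
    valid = grid.dropna(subset=["cv_rmse"])
    if valid.empty:
        raise ValueError("every grid point failed; no valid (threshold, m) choice")
    # argmin with ties broken toward larger threshold, then smaller m
    best_rmse = valid["cv_rmse"].min()
    tied = valid[np.isclose(valid["cv_rmse"], best_rmse, rtol=0, atol=1e-12)]
    tied = tied.sort_values(["threshold", "n_components"], ascending=[False, True])
    chosen = tied.iloc[0]
    return SupervisedPCChoice(
        grid=grid,
        threshold=float(chosen["threshold"]),
        n_components=int(chosen["n_components"]),
    )
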