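"""Latent-component regression: single-response PLS (NIPALS) and PCR.

PLS is implemented natively as NIPALS for one response, which is
closed-form per component (no iteration or tolerance): with current
deflated data X_a, y_a,

    w_a = X_a' y_a / ||X_a' y_a||      (unit weight vector)
    t_a = X_a w_a                       (scores)
    p_a = X_a' t_a / t_a' t_a           (X loadings)
    q_a = y_a' t_a / t_a' t_a           (y loading)
    X_{a+1} = X_a - t_a p_a'            (deflation)

The compact coefficient vector b = W (P'W)^{-1} q reproduces the staged
component predictions in a single matrix product. Variable importance in
projection (VIP) accumulates over all retained components,

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a't_a,

and satisfies sum_j VIP_j^2 = p by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModel",
    "PCRModel",
    "fit_pls",
    "fit_pcr",
    "predict",
    "compute_vip",
    "select_by_vip",
    "model_to_json",
    "model_from_json",
]


def _as_matrix(X, probe_ids=None):
    """Accept ExpressionMatrix / DataFrame (probes x samples) or ndarray
    (samples x probes); return (samples x probes ndarray, probe index)."""
    from .expression import ExpressionMatrix

    if isinstance(X, ExpressionMatrix):
        return X.values.to_numpy().T, X.values.index
    if isinstance(X, pd.DataFrame):
        return X.to_numpy().T, X.index
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    if probe_ids is None:
        probe_ids = pd.Index([f"x{j}" for j in range(arr.shape[1])])
    return arr, pd.Index(probe_ids)


@dataclass
class PLSModel:
    """Fitted single-response PLS model with A latent components."""

    A: int
    W: np.ndarray  # probes x A unit weight vectors
    T: np.ndarray  # samples x A scores (training)
    P: np.ndarray  # probes x A X-loadings
    q: np.ndarray  # A y-loadings
    b: np.ndarray  # probes, compact coefficients
    intercept: float
    x_mean: np.ndarray
    training_probe_ids: pd.Index
    vip: Optional[pd.Series] = None


@dataclass
class PCRModel:
    """Principal-components regression with m retained components."""

    m: int
    rotation: np.ndarray  # probes x m
    gamma: np.ndarray  # m component coefficients
    b: np.ndarray
    intercept: float
    x_mean: np.ndarray
    training_probe_ids: pd.Index


def fit_pls(X, y, A: int, probe_ids=None) -> PLSModel:
    """Fit PLS1 with A components by NIPALS.

    X may be an ExpressionMatrix / DataFrame (probes x samples) or an
    ndarray (samples x probes). Columns are centered internally; the
    intercept is the training mean of y.
    """
    Xm, pidx = _as_matrix(X, probe_ids)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if A < 1:
        raise ValueError("A must be >= 1")
    max_possible = min(n - 1, p)
    if A > max_possible:
        raise ValueError(
            f"A={A} exceeds the achievable maximum min(n-1, p)={max_possible}"
        )
    x_mean = Xm.mean(axis=0)
    Xa = Xm - x_mean
    ybar = float(y.mean())
    ya = y - ybar

    scale = max(float(np.abs(Xa).max()), 1.0)
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            raise ValueError(
                f"X (or its y-covariance) is exhausted after {a} components; "
                f"requested A={A}, achievable maximum here is {a}"
            )
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale) ** 2:
            raise ValueError(
                f"rank exhausted after {a} components; achievable maximum is {a}"
            )
        pa = Xa.T @ t / tt
        qa = float(ya @ t) / tt
        Xa = Xa - np.outer(t, pa)
        ya = ya - qa * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pa, qa

    b = W @ np.linalg.solve(P.T @ W, q)
    model = PLSModel(
        A=A, W=W, T=T, P=P, q=q, b=b, intercept=ybar, x_mean=x_mean,
        training_probe_ids=pidx,
    )
    model.vip = compute_vip(model)
    return model


def fit_pcr(X, y, m: int, probe_ids=None) -> PCRModel:
    """Principal-components regression: OLS of y on the first m PC scores.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    Xm, pidx = _as_matrix(X, probe_ids)
    y = np.asarray(y, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    x_mean = Xm.mean(axis=0)
    Xc = Xm - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > (s[0] if s.size else 0) * 1e-12).sum())
    if m > rank:
        raise ValueError(f"m={m} exceeds rank(X)={rank}")
    V = Vt[:m].T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(m)])
    V = V * flip
    T = Xc @ V
    design = np.column_stack([np.ones(len(T)), T])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    gamma = coef[1:]
    b = V @ gamma
    return PCRModel(
        m=m, rotation=V, gamma=gamma, b=b, intercept=float(coef[0]),
        x_mean=x_mean, training_probe_ids=pidx,
    )


def predict(model, Xnew, probe_ids=None) -> np.ndarray:
    """Predicted log2 SUV for new (already training-standardized) samples.

    Probe identities must match the training probes exactly; a mismatch
    reports the symmetric difference.
    """
    Xm, pidx = _as_matrix(Xnew, probe_ids)
    train = model.training_probe_ids
    if len(pidx) != len(train) or not pidx.equals(train):
        if set(pidx) == set(train):
            # same probes, different order: realign to training order
            Xm = Xm[:, pd.Index(pidx).get_indexer(train)]
        else:
            only_new = sorted(set(pidx) - set(train))
            only_train = sorted(set(train) - set(pidx))
            raise KeyError(
                f"probe mismatch: {len(only_new)} only in new data "
                f"(e.g. {only_new[:3]}), {len(only_train)} only in training "
                f"(e.g. {only_train[:3]})"
            )
    return model.intercept + (Xm - model.x_mean) @ model.b


def compute_vip(model: PLSModel) -> pd.Series:
    """VIP per probe, accumulated over all retained components."""
    if model.W is None or model.q is None:
        raise ValueError("model is not fitted")
    p = model.W.shape[0]
    ss = model.q**2 * (model.T**2).sum(axis=0)  # q_a^2 t_a't_a
    wnorm2 = (model.W**2).sum(axis=0)  # = 1 per component, kept for clarity
    contrib = (model.W**2 / wnorm2) @ ss
    vip = np.sqrt(p * contrib / ss.sum())
    return pd.Series(vip, index=model.training_probe_ids, name="vip")


def select_by_vip(
    vip: pd.Series, cutoff: float = 1.0, gene_symbols: Optional[pd.Series] = None
) -> dict:
    """Probes with VIP >= cutoff, plus the annotation-balance report.

    When gene symbols are supplied, reports the fraction of unannotated
    probes inside and outside the selection and a Fisher exact test that
    the selection is not enriched for annotated probes.
    """
    selected = vip.index[vip >= cutoff]
    if len(selected) == 0:
        warnings.warn(f"no probe reaches VIP >= {cutoff}")
    out = {"selected": selected, "cutoff": cutoff, "n_selected": int(len(selected))}
    if gene_symbols is not None:
        sym = gene_symbols.reindex(vip.index)
        unann = sym.isna()
        in_sel = vip.index.isin(selected)
        table = [
            [int((unann & in_sel).sum()), int((~unann & in_sel).sum())],
            [int((unann & ~in_sel).sum()), int((~unann & ~in_sel).sum())],
        ]
        out["n_unannotated_selected"] = table[0][0]
        out["frac_unannotated_selected"] = (
            table[0][0] / len(selected) if len(selected) else float("nan")
        )
        out["frac_unannotated_overall"] = float(unann.mean())
        out["fisher_p"] = float(stats.fisher_exact(table)[1])
    return out


def model_to_json(model: PLSModel, standardization_params: Optional[pd.DataFrame] = None) -> str:
    """Portable JSON of a fitted PLS signature."""
    payload = {
        "kind": "pls",
        "A": model.A,
        "probe_ids": list(model.training_probe_ids),
        "intercept": model.intercept,
        "b": model.b.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "x_mean": model.x_mean.tolist(),
        "vip": None if model.vip is None else model.vip.tolist(),
    }
    if standardization_params is not None:
        payload["standardization"] = {
            "mean": standardization_params["mean"].tolist(),
            "sd": standardization_params["sd"].tolist(),
        }
    return json.dumps(payload)


def model_from_json(text: str) -> tuple[PLSModel, Optional[pd.DataFrame]]:
    d = json.loads(text)
    if d.get("kind") != "pls":
        raise ValueError("not a serialized PLS signature")
    pidx = pd.Index(d["probe_ids"])
    model = PLSModel(
        A=d["A"],
        W=np.asarray(d["W"]),
        T=np.zeros((0, d["A"])),
        P=np.asarray(d["P"]),
        q=np.asarray(d["q"]),
        b=np.asarray(d["b"]),
        intercept=d["intercept"],
        x_mean=np.asarray(d["x_mean"]),
        training_probe_ids=pidx,
        vip=None if d.get("vip") is None else pd.Series(d["vip"], index=pidx),
    )
    params = None
    if "standardization" in d:
        params = pd.DataFrame(
            {
                "mean": d["standardization"]["mean"],
                "sd": d["standardization"]["sd"],
            },
            index=pidx,
        )
    return model, params
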