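"""Model evaluation: repeated CV, paired comparisons, external validation.

Four regression families are compared on identical resamples: PLS,
principal-components regression, support vector regression and random
forest, each refitting standardization and univariate feature selection
inside every training fold (no leakage). RMSE is always on the log2-SUV
modeling scale; R^2 is the squared Pearson correlation between observed
and predicted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, standardize, apply_standardization
from .feature_select import univariate_coefficients, select_probes
from . import latent
from .pet_quant import OutlierFences, classify_observation, ObservationClass

__all__ = [
    "rmse",
    "r_squared",
    "SignatureModel",
    "make_model",
    "repeated_cv",
    "summarize_resamples",
    "compare_models",
    "external_validate",
    "stability_sweep",
]


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation of observed vs predicted.

    Returns NaN (with a warning) when either vector is constant, so
    degenerate resamples can be excluded from summaries explicitly.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("constant vector: R^2 undefined for this resample")
        return float("nan")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


class Regressor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Regressor": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


class _PLSCore:
    def __init__(self, n_components: int):
        self.A = n_components

    def fit(self, X, y):
        self.model_ = latent.fit_pls(X, y, min(self.A, min(X.shape[0] - 1, X.shape[1])))
        return self

    def predict(self, X):
        return latent.predict(self.model_, X)


class _PCRCore:
    def __init__(self, m: int):
        self.m = m

    def fit(self, X, y):
        self.model_ = latent.fit_pcr(X, y, min(self.m, min(X.shape[0] - 1, X.shape[1])))
        return self

    def predict(self, X):
        return latent.predict(self.model_, X)


@dataclass
class SignatureModel:
    """Full signature pipeline behind the fit/predict contract.

    fit() standardizes the training probes, scores them univariately,
    selects by |beta| threshold (or top_n), and fits the wrapped
    regressor on the reduced standardized matrix. predict() applies the
    frozen standardization to new samples. Deterministic given its seed.
    """

    name: str
    core_factory: Callable[[], Regressor]
    threshold: Optional[float] = None
    top_n: Optional[int] = None
    sign: Optional[str] = None  # None | "positive" | "negative"

    def fit(self, X: ExpressionMatrix, y) -> "SignatureModel":
        if (self.threshold is None) == (self.top_n is None):
            raise ValueError("specify exactly one of threshold / top_n")
        y = np.asarray(y, dtype=float)
        Xstd = standardize(X)
        table = univariate_coefficients(Xstd, y)
        if self.top_n is not None:
            sel = table.sort_values("rank").index[: self.top_n]
        else:
            sel = select_probes(table, self.threshold)
        if self.sign == "positive":
            sel = sel[table.loc[sel, "beta"] > 0]
        elif self.sign == "negative":
            sel = sel[table.loc[sel, "beta"] < 0]
        if len(sel) == 0:
            raise ValueError(f"{self.name}: empty probe selection")
        self.selected_ = pd.Index(sel)
        self.params_ = Xstd.standardization_params.loc[self.selected_]
        self.score_table_ = table
        Xr = Xstd.values.loc[self.selected_].to_numpy().T
        self.core_ = self.core_factory().fit(Xr, y)
        return self

    def predict(self, X: ExpressionMatrix) -> np.ndarray:
        missing = self.selected_.difference(X.probe_ids)
        if len(missing):
            raise KeyError(f"new data lacks {len(missing)} training probes")
        sub = X.subset_probes(self.selected_)
        Xs = apply_standardization(sub, self.params_)
        return np.asarray(self.core_.predict(Xs.values.to_numpy().T), dtype=float)


def make_model(kind: str, *, threshold=None, top_n=None, sign=None, seed: int = 0,
               n_components: int = 3, pcr_components: int = 18, **kw) -> SignatureModel:
    """Factory for the four compared model families.

    kind: 'pls' (default 3 components), 'pcr' (default 18), 'svm'
    (RBF support vector regression), 'rf' (random forest).
    """
    kind = kind.lower()
    if kind == "pls":
        factory = lambda: _PLSCore(n_components)
        name = f"PLS-{n_components}"
    elif kind == "pcr":
        factory = lambda: _PCRCore(pcr_components)
        name = f"PCR-{pcr_components}"
    elif kind == "svm":
        from sklearn.svm import SVR

        factory = lambda: SVR(**kw) if kw else SVR()
        name = "SVM"
    elif kind == "rf":
        from sklearn.ensemble import RandomForestRegressor

        factory = lambda: RandomForestRegressor(
            n_estimators=kw.pop("n_estimators", 100), random_state=seed, **kw
        )
        name = "RF"
    else:
        raise ValueError(f"unknown model kind: {kind}")
    return SignatureModel(name=name, core_factory=factory, threshold=threshold,
                          top_n=top_n, sign=sign)


def _fold_partitions(n: int, k: int, repeats: int, seed: int):
    """Seeded random partitions, identical for every model (paired)."""
    rng = np.random.default_rng(seed)
    out = []
    for r in range(repeats):
        perm = rng.permutation(n)
        out.append([(r, f, fold) for f, fold in enumerate(np.array_split(perm, k))])
    return out


def repeated_cv(
    models: Sequence[SignatureModel],
    X: ExpressionMatrix,
    y,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV repeated ``repeats`` times; k x repeats resamples per model.

    All models see identical fold partitions, so the resamples are paired
    across models. A model failure on a fold is recorded (rmse/r2 NaN,
    error message in the ``error`` column) and surfaced, not fatal.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError("k exceeds n")
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique")
    rows = []
    for partition in _fold_partitions(n, k, repeats, seed):
        for r, f, fold in partition:
            tr = np.setdiff1d(np.arange(n), fold)
            Xtr = ExpressionMatrix(values=X.values.iloc[:, tr],
                                   gene_symbols=X.gene_symbols)
            Xte = ExpressionMatrix(values=X.values.iloc[:, fold],
                                   gene_symbols=X.gene_symbols)
            for model in models:
                row = {"model": model.name, "repeat": r, "fold": f,
                       "resample": r * k + f, "n_test": len(fold)}
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model.fit(Xtr, y[tr])
                        pred = model.predict(Xte)
                    row["rmse"] = rmse(y[fold], pred)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row["r2"] = r_squared(y[fold], pred)
                    row["error"] = None
                except Exception as exc:  # recorded, excluded, surfaced
                    row.update(rmse=np.nan, r2=np.nan, error=str(exc))
                rows.append(row)
    table = pd.DataFrame(rows)
    n_fail = int(table["error"].notna().sum())
    if n_fail:
        warnings.warn(f"{n_fail} resample(s) failed and were excluded from metrics")
    return table


def summarize_resamples(resamples: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean, SD, empirical and parametric 95% intervals."""
    rows = []
    for name, g in resamples.groupby("model", sort=False):
        row = {"model": name, "n_resamples": int(len(g))}
        for metric in ("rmse", "r2"):
            v = g[metric].dropna()
            row[f"{metric}_mean"] = float(v.mean())
            row[f"{metric}_sd"] = float(v.std(ddof=1))
            row[f"{metric}_q025"] = float(v.quantile(0.025))
            row[f"{metric}_q975"] = float(v.quantile(0.975))
            half = 1.96 * v.std(ddof=1)
            row[f"{metric}_ci_lo"] = float(v.mean() - half)
            row[f"{metric}_ci_hi"] = float(v.mean() + half)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(resamples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-test on RMSE and Wilcoxon signed-rank on R^2.

    Both p-values are Bonferroni-multiplied by the number of pairs
    actually compared and capped at 1. Requires paired resamples (same
    fold partition for every model).
    """
    names = list(dict.fromkeys(resamples["model"]))
    wide_rmse = resamples.pivot(index="resample", columns="model", values="rmse")
    wide_r2 = resamples.pivot(index="resample", columns="model", values="r2")
    if wide_rmse.isna().any().any():
        raise ValueError("unpaired or failed resamples; comparison requires "
                         "complete paired metrics")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    factor = len(pairs)
    rows = []
    for a, b in pairs:
        da = wide_rmse[a] - wide_rmse[b]
        degenerate = bool(np.allclose(da, 0))
        if degenerate:
            p_rmse = 1.0
            p_r2 = 1.0
        else:
            p_rmse = float(stats.ttest_rel(wide_rmse[a], wide_rmse[b]).pvalue)
            dr = (wide_r2[a] - wide_r2[b]).dropna()
            p_r2 = (
                1.0
                if np.allclose(dr, 0)
                else float(stats.wilcoxon(dr).pvalue)
            )
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "rmse_p_adj": min(1.0, p_rmse * factor),
                "r2_p_adj": min(1.0, p_r2 * factor),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def external_validate(
    model: SignatureModel,
    Xval: ExpressionMatrix,
    yval,
    fences: OutlierFences,
) -> dict:
    """Frozen-model validation with influential-observation accounting.

    ``fences`` are IQR fences of the raw training SUVmean35. Outliers are
    excluded a priori from every RMSE (as in cohort curation); influential
    observations are reported both ways: included in ``rmse_all``,
    excluded from ``rmse_excluding_influential``. The per-sample table
    carries measured and predicted SUV on both scales plus the
    predicted/measured fold ratio.
    """
    yval = pd.Series(np.asarray(yval, dtype=float), index=Xval.sample_ids)
    pred_log2 = pd.Series(model.predict(Xval), index=Xval.sample_ids)
    suv = 2.0**yval
    classes = suv.map(lambda v: classify_observation(float(v), fences).value)
    table = pd.DataFrame(
        {
            "measured_suv": suv,
            "predicted_suv": 2.0**pred_log2,
            "measured_log2_suv": yval,
            "predicted_log2_suv": pred_log2,
            "pred_over_measured": (2.0**pred_log2) / suv,
            "classification": classes,
        }
    )
    keep = ~classes.isin(
        [ObservationClass.LOW_OUTLIER.value, ObservationClass.HIGH_OUTLIER.value]
    )
    infl = classes == ObservationClass.INFLUENTIAL.value
    used = table[keep]
    strict = table[keep & ~infl]
    out = {
        "rmse_all": rmse(used["measured_log2_suv"], used["predicted_log2_suv"]),
        "n_all": int(len(used)),
        "n_outliers_excluded": int((~keep).sum()),
        "n_influential": int(infl.sum()),
        "per_sample": table,
    }
    out["rmse_excluding_influential"] = (
        rmse(strict["measured_log2_suv"], strict["predicted_log2_suv"])
        if len(strict)
        else float("nan")
    )
    out["n_excluding"] = int(len(strict))
    return out


def stability_sweep(
    X: ExpressionMatrix,
    y,
    Xval: ExpressionMatrix,
    yval,
    thresholds: Sequence[float],
    sign_variants: Sequence[str] = ("positive", "negative"),
    sign_threshold: Optional[float] = None,
    n_components: int = 3,
    fences: Optional[OutlierFences] = None,
) -> pd.DataFrame:
    """Validation RMSE of signatures at varying |beta| thresholds and signs.

    Each variant retrains feature selection plus PLS on the training data
    only and is evaluated on the validation set with and without
    influential observations. A variant whose selection is empty is
    recorded as failed, not fatal.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if fences is None:
        fences = _fences_from_log2(y)
    if sign_threshold is None:
        sign_threshold = thresholds[len(thresholds) // 2]
    variants = [("mixed", th) for th in thresholds]
    variants += [(s, sign_threshold) for s in sign_variants]
    rows = []
    for sign, th in variants:
        label = f"{sign}@{th:g}"
        model = make_model(
            "pls",
            threshold=th,
            sign=None if sign == "mixed" else sign,
            n_components=n_components,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, y)
                res = external_validate(model, Xval, yval, fences)
            rows.append(
                {
                    "variant": label,
                    "sign": sign,
                    "threshold": th,
                    "n_probes": len(model.selected_),
                    "rmse_with_influential": res["rmse_all"],
                    "rmse_without_influential": res["rmse_excluding_influential"],
                    "error": None,
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "variant": label,
                    "sign": sign,
                    "threshold": th,
                    "n_probes": 0,
                    "rmse_with_influential": np.nan,
                    "rmse_without_influential": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


def _fences_from_log2(y) -> OutlierFences:
    from .pet_quant import outlier_fences

    return outlier_fences(2.0 ** np.asarray(y, dtype=float))
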