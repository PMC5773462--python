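"""Unsupervised check that signature probes stratify samples by uptake.

Samples are clustered hierarchically (complete linkage) on the Spearman
correlation distance 1 - rho between sample expression profiles, the
tree is cut into k groups (k = 5 by default), and the raw SUVmean35 is
compared across clusters by one-way ANOVA plus unadjusted pairwise
t-tests. Running the identical pipeline on the full unselected probe set
serves as the negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix, standardize

__all__ = [
    "ClusterResult",
    "correlation_distance",
    "hierarchical_clusters",
    "cluster_phenotype_anova",
    "cluster_pipeline",
    "control_clustering",
]


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # sample -> cluster label in 1..k
    stats: pd.DataFrame  # per-cluster n, mean, sd, min, max of raw SUV
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # cluster_a, cluster_b, t_p (unadjusted)


def correlation_distance(X) -> pd.DataFrame:
    """Sample-by-sample distance 1 - Spearman rho between columns.

    Ties receive average ranks. A constant column has no rank variation
    and is reported by name.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else X
    if values.shape[0] < 2:
        raise ValueError("need at least 2 probes")
    arr = values.to_numpy()
    const = arr.std(axis=0) == 0
    if const.any():
        bad = list(values.columns[const])
        raise ValueError(f"constant expression column(s): {bad}")
    ranks = np.apply_along_axis(stats.rankdata, 0, arr)
    corr = np.corrcoef(ranks.T)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=values.columns, columns=values.columns)


def hierarchical_clusters(D: pd.DataFrame, k: int = 5) -> pd.Series:
    """Complete-linkage agglomeration of a distance matrix, cut at k."""
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    arr = D.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    Z = linkage(squareform(arr, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=D.index, name="cluster")


def cluster_phenotype_anova(labels: pd.Series, suv_raw) -> ClusterResult:
    """One-way ANOVA of raw SUV across clusters, plus pairwise t-tests.

    Pairwise p-values are reported unadjusted. Size-1 clusters enter the
    ANOVA but are excluded from their pairwise tests with a warning.
    """
    suv = pd.Series(np.asarray(suv_raw, dtype=float), index=labels.index)
    ks = sorted(labels.unique())
    if len(ks) < 2:
        raise ValueError("ANOVA requires at least 2 clusters")
    groups = {g: suv[labels == g].to_numpy() for g in ks}
    f, p = stats.f_oneway(*groups.values())
    rows = [
        {
            "cluster": g,
            "n": len(v),
            "mean_suv": float(v.mean()),
            "sd_suv": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            "min_suv": float(v.min()),
            "max_suv": float(v.max()),
        }
        for g, v in groups.items()
    ]
    singletons = [g for g, v in groups.items() if len(v) < 2]
    if singletons:
        warnings.warn(
            f"cluster(s) {singletons} have a single sample; excluded from "
            f"pairwise t-tests"
        )
    pair_rows = []
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            if a in singletons or b in singletons:
                continue
            t, tp = stats.ttest_ind(groups[a], groups[b])
            pair_rows.append({"cluster_a": a, "cluster_b": b, "t_p": float(tp)})
    return ClusterResult(
        k=len(ks),
        labels=labels,
        stats=pd.DataFrame(rows),
        anova_f=float(f),
        anova_p=float(p),
        pairwise=pd.DataFrame(pair_rows, columns=["cluster_a", "cluster_b", "t_p"]),
    )


def cluster_pipeline(X, suv_raw, k: int = 5, *, standardize_probes: bool = True) -> ClusterResult:
    """Distance -> complete-linkage tree cut at k -> per-cluster SUV ANOVA."""
    if isinstance(X, ExpressionMatrix):
        Xm = standardize(X) if (standardize_probes and not X.standardized) else X
        values = Xm.values
    else:
        values = X
    D = correlation_distance(values)
    labels = hierarchical_clusters(D, k=k)
    return cluster_phenotype_anova(labels, suv_raw)


def control_clustering(X_all_probes, suv_raw, k: int = 5) -> ClusterResult:
    """Negative control: the identical pipeline on the full probe set."""
    return cluster_pipeline(X_all_probes, suv_raw, k=k)
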