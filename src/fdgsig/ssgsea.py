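"""Single-sample GSEA and gene-set phenotype correlation.

Probe-level intensities are first summarized to one row per gene symbol
(keeping, for multi-probe genes, the probe with the largest intensity;
probes without a symbol are dropped). Per sample, genes are ranked by
expression and a gene set's enrichment score is the integrated gap
between the rank-weighted cumulative distribution of in-set genes
(weights |rank|^alpha, alpha = 0.25 by default) and the uniform
cumulative distribution of out-of-set genes. Scores are optionally
normalized by the global max - min across the whole score matrix, and
are finally correlated per set with the log2-transformed SUV (Pearson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "summarize_probes_to_genes",
    "ssgsea_scores",
    "correlate_scores_with_phenotype",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with uppercase-normalized symbols."""

    sets: dict
    source: str = ""
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            norm[name] = members
        self.sets = norm

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno} "
                    f"(expected name, description, >=1 member)"
                )
            name, description, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: gene set {name!r} on line {lineno} is empty")
            uniq = list(dict.fromkeys(m.upper() for m in members))
            if len(uniq) < len(members):
                warnings.warn(f"gene set {name!r}: duplicate members deduplicated")
            sets[name] = frozenset(uniq)
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def summarize_probes_to_genes(
    X: ExpressionMatrix, annotation: Optional[pd.Series] = None, mode: str = "probe"
) -> pd.DataFrame:
    """Collapse probes to one row per gene symbol.

    mode='probe' (default): for a multi-probe gene keep the single probe
    with the largest mean intensity across samples (one coherent probe
    per gene). mode='sample': per-sample maximum over the gene's probes.
    Probes without a symbol are dropped.
    """
    symbols = annotation if annotation is not None else X.gene_symbols
    if symbols is None:
        raise ValueError("no probe annotation available")
    symbols = symbols.reindex(X.probe_ids)
    keep = symbols.notna()
    if not keep.any():
        raise ValueError("no annotated probe: gene-level matrix would be empty")
    vals = X.values.loc[keep]
    sym = symbols[keep].str.upper()
    if mode == "probe":
        order = vals.mean(axis=1)
        best = order.groupby(sym).idxmax()
        out = vals.loc[best]
        out.index = best.index
    elif mode == "sample":
        out = vals.groupby(sym).max()
    else:
        raise ValueError("mode must be 'probe' or 'sample'")
    out.index.name = "gene_symbol"
    return out.sort_index()


def _sample_scores(expr: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score of one sample for one membership mask.

    Genes are walked in decreasing expression (ties broken by stable
    input order); rank weights are rank^alpha with rank N for the
    highest-expressed gene.
    """
    n = len(expr)
    order = np.argsort(-expr, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # N .. 1 along the walk
    mask = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(mask, w, 0.0)
    total_in = w_in.sum()
    n_out = n - mask.sum()
    cum_in = np.cumsum(w_in) / total_in
    cum_out = np.cumsum(~mask) / n_out if n_out > 0 else np.zeros(n)
    return float(np.sum(cum_in - cum_out))


def ssgsea_scores(
    gene_expr: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA score matrix (gene set x sample).

    A set disjoint from the expressed genes gets NaN scores with a
    warning, not an error. With ``normalize``, all scores are divided by
    the global (max - min) of the raw score matrix.
    """
    if gene_expr.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    genes = pd.Index(gene_expr.index.str.upper())
    arr = gene_expr.to_numpy()
    out = np.full((len(collection.sets), gene_expr.shape[1]), np.nan)
    for i, (name, members) in enumerate(collection.sets.items()):
        mask = genes.isin(members)
        if not mask.any():
            warnings.warn(f"gene set {name!r} shares no gene with the matrix")
            continue
        if mask.all():
            # out-of-set ECDF is empty; score is the in-set cumulative sum
            pass
        for j in range(arr.shape[1]):
            out[i, j] = _sample_scores(arr[:, j], mask, alpha)
    scores = pd.DataFrame(out, index=list(collection.sets), columns=gene_expr.columns)
    if normalize:
        lo, hi = np.nanmin(out), np.nanmax(out)
        if hi > lo:
            scores = scores / (hi - lo)
    return scores


def correlate_scores_with_phenotype(
    scores: pd.DataFrame, log2_suv: pd.Series
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each gene set's scores with log2 SUV."""
    common = scores.columns.intersection(log2_suv.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned samples")
    y = log2_suv.loc[common].to_numpy()
    rows = []
    for name, row in scores[common].iterrows():
        v = row.to_numpy()
        if np.isnan(v).any():
            rows.append({"geneset": name, "pearson_r": np.nan, "p_value": np.nan})
            continue
        r, p = stats.pearsonr(v, y)
        rows.append({"geneset": name, "pearson_r": float(r), "p_value": float(p)})
    return (
        pd.DataFrame(rows)
        .sort_values("pearson_r", ascending=False)
        .reset_index(drop=True)
    )
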