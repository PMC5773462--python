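"""Probes-by-samples expression container and probe standardization.

The matrix is stored probes in rows, samples in columns (the layout of a
microarray heatmap). Standardization is per probe with the n-1 variance
convention, and the training means/sds are frozen on the object so that
external validation samples can be brought onto the training scale with
:func:`apply_standardization`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "standardize", "apply_standardization"]


@dataclass
class ExpressionMatrix:
    """Expression intensities with probe annotation.

    values: DataFrame, probes (rows) x samples (columns).
    gene_symbols: Series indexed by probe id; NaN/None marks probes
        without a symbol (they are first-class citizens throughout).
    standardized: True when each probe row has training mean 0, sd 1.
    standardization_params: per-probe (mean, sd) frozen from the
        training cohort; present on standardized matrices and on
        matrices produced by ``apply_standardization``.
    """

    values: pd.DataFrame
    gene_symbols: Optional[pd.Series] = None
    standardized: bool = False
    standardization_params: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        sub = self.values.loc[list(probe_ids)]
        return ExpressionMatrix(
            values=sub,
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[sub.index],
            standardized=self.standardized,
            standardization_params=(
                None
                if self.standardization_params is None
                else self.standardization_params.loc[sub.index]
            ),
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path, annotation: Optional[pd.Series] = None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, gene_symbols=annotation)


def standardize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each probe to mean 0, sd 1 (n-1 convention).

    Constant probes cannot be standardized; they are removed with a
    warning and listed in the returned matrix's ``standardization_params``
    only by their absence. Idempotent on already-standardized input.
    """
    if X.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    vals = X.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(
            f"removed {int(constant.sum())} constant probe(s) during standardization"
        )
        vals = vals.loc[~constant]
        mean = mean.loc[~constant]
        sd = sd.loc[~constant]
    std_vals = vals.sub(mean, axis=0).div(sd, axis=0)
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return ExpressionMatrix(
        values=std_vals,
        gene_symbols=None if X.gene_symbols is None else X.gene_symbols.loc[std_vals.index],
        standardized=True,
        standardization_params=params,
    )


def apply_standardization(
    Xnew: ExpressionMatrix, params: pd.DataFrame
) -> ExpressionMatrix:
    """Bring new samples onto a frozen training scale.

    Every probe of ``Xnew`` must appear in ``params`` (the training
    means/sds); validation rows need not end up with mean 0.
    """
    missing = Xnew.values.index.difference(params.index)
    if len(missing) > 0:
        raise KeyError(
            f"standardization params missing for {len(missing)} probe(s): "
            f"{missing[:5].tolist()}"
        )
    p = params.loc[Xnew.values.index]
    std_vals = Xnew.values.sub(p["mean"], axis=0).div(p["sd"], axis=0)
    return ExpressionMatrix(
        values=std_vals,
        gene_symbols=Xnew.gene_symbols,
        standardized=True,
        standardization_params=p,
    )
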