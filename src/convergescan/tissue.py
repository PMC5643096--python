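"""Tissue-specific gene sets from replicate-level expression profiles.

A gene is *specific* to a tissue of interest when its expression in that
tissue's replicates is significantly higher than in all other samples
(Welch t-test at level alpha) and the same is not true for any other tissue
of interest — so lens-specific genes are elevated in lens and only in lens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSet

__all__ = [
    "ExpressionMatrix",
    "CorrelationResult",
    "tissue_specific_sets",
    "specificity_acceleration_correlation",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample -> tissue labels."""

    values: pd.DataFrame
    tissues: pd.Series  # index = sample ids, value = tissue label
    log_scale: bool = True

    def __post_init__(self):
        self.tissues = pd.Series(self.tissues)
        if list(self.values.columns) != list(self.tissues.index):
            self.tissues = self.tissues.reindex(self.values.columns)
        if self.tissues.isna().any():
            missing = list(self.tissues.index[self.tissues.isna()])
            raise ValueError(f"samples without tissue labels: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def replicates(self, tissue: str) -> pd.DataFrame:
        if tissue not in set(self.tissues):
            raise ValueError(f"tissue {tissue!r} not present in sample labels")
        return self.values.loc[:, self.tissues.eq(tissue).to_numpy()]


def _elevated(expr: ExpressionMatrix, tissue: str, alpha: float) -> np.ndarray:
    """Genes significantly higher in `tissue` than in all other samples."""
    mask = expr.tissues.eq(tissue).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"tissue {tissue!r} has fewer than two replicates")
    X = expr.values.to_numpy()
    a = X[:, mask]
    b = X[:, ~mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes -> nan
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    higher = a.mean(axis=1) > b.mean(axis=1)
    return np.nan_to_num(p, nan=1.0) < alpha, higher


def tissue_specific_sets(
    expr: ExpressionMatrix,
    tissues_of_interest: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, GeneSet]:
    """One gene set per tissue of interest; sets are disjoint by construction.

    Gene g belongs to set(T) iff the Welch t-test of T's replicates against
    all other samples is significant at ``alpha`` with higher mean in T, and
    no other tissue of interest shows the same significant elevation.
    """
    sig_up = {}
    for tissue in tissues_of_interest:
        sig, higher = _elevated(expr, tissue, alpha)
        sig_up[tissue] = sig & higher
    genes = expr.values.index.to_numpy()
    out = {}
    for tissue in tissues_of_interest:
        exclusive = sig_up[tissue].copy()
        for other in tissues_of_interest:
            if other != tissue:
                exclusive &= ~sig_up[other]
        members = frozenset(genes[exclusive])
        if members:
            out[tissue] = GeneSet(name=tissue, members=members)
    return out


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    undefined: bool = False


def specificity_acceleration_correlation(
    spec_score: Mapping[str, float] | pd.Series,
    accel_score: Mapping[str, float] | pd.Series,
) -> CorrelationResult:
    """Spearman rank correlation between tissue specificity and acceleration.

    Scores are caller-supplied per gene; only genes with both scores enter.
    Constant inputs leave the correlation undefined (flagged, rho = NaN).
    """
    a = pd.Series(spec_score, dtype=float)
    b = pd.Series(accel_score, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least three genes with both scores")
    x = a.loc[common].to_numpy()
    y = b.loc[common].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=np.nan, p=np.nan, n=len(common), undefined=True)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(common))
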