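"""Downstream summaries of a scan: enrichment, ranks, precision-recall, profiles.

The background for every enrichment test is restricted to the elements that
were actually scored in the scan, so set membership files are intersected
with the scored universe before the hypergeometric tail is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rer import RERMatrix

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_tail",
    "enrich_gene_sets",
    "rank_histogram",
    "precision_recall_curve",
    "species_mean_rer",
    "read_gene_sets",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper hypergeometric tail for k set members among n hits.

    N: background size; K: set members in background; n: hits; k: set
    members among hits; fold = (k/n) / (K/N); p = P(X >= k).
    """

    name: str
    N: int
    K: int
    n: int
    k: int
    fold: float
    p: float


def hypergeom_tail(N: int, K: int, n: int, k: int, name: str = "") -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), with fold enrichment."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric margins N={N} K={K} n={n} k={k}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(p, 0.0))
    fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
    return EnrichmentResult(name=name, N=N, K=K, n=n, k=k, fold=fold, p=p)


def enrich_gene_sets(
    hits: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """Test each set for over-representation among hits; BH-correct across sets."""
    bg = frozenset(background)
    hit = frozenset(hits) & bg
    rows = []
    for gs in sets:
        members = gs.members & bg
        if not members:
            continue
        res = hypergeom_tail(len(bg), len(members), len(hit), len(members & hit), gs.name)
        rows.append(res.__dict__)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame


def _sorted_ids(pvalues: Mapping[str, float] | pd.Series) -> list[str]:
    series = pd.Series(pvalues)
    order = np.lexsort((series.index.astype(str), series.to_numpy()))
    return list(series.index[order])


def rank_histogram(pvalues: Mapping[str, float] | pd.Series, gene_set: GeneSet) -> np.ndarray:
    """1-based ranks of set members when elements are sorted by ascending p.

    Ties are broken by element id so the ranking is deterministic.
    """
    ordered = _sorted_ids(pvalues)
    members = gene_set.members
    ranks = [i for i, eid in enumerate(ordered, start=1) if eid in members]
    if not ranks:
        raise ValueError(f"no member of {gene_set.name!r} among scored elements")
    return np.array(ranks)


def precision_recall_curve(
    pvalues: Mapping[str, float] | pd.Series, gene_set: GeneSet
) -> pd.DataFrame:
    """Precision and recall of set membership at every observed p threshold."""
    series = pd.Series(pvalues)
    in_set = series.index.isin(gene_set.members)
    total = int(in_set.sum())
    if total == 0:
        raise ValueError(f"no member of {gene_set.name!r} among scored elements")
    order = np.lexsort((series.index.astype(str), series.to_numpy()))
    p = series.to_numpy()[order]
    hits = np.cumsum(in_set[order])
    n = np.arange(1, p.size + 1)
    # collapse to distinct thresholds, keeping the last (complete) count at each
    last = np.r_[p[1:] != p[:-1], True]
    return pd.DataFrame(
        {
            "threshold": p[last],
            "precision": hits[last] / n[last],
            "recall": hits[last] / total,
        }
    )


def species_mean_rer(rer: RERMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-species mean terminal-branch RER over the set's elements.

    Species with no observation in any set member are NaN.
    """
    frame = rer.terminal_frame()
    rows = frame.loc[frame.index.isin(gene_set.members)]
    if rows.empty:
        raise ValueError(f"no member of {gene_set.name!r} present in the RER matrix")
    return rows.mean(axis=0, skipna=True)


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from GMT or two-column ``set<TAB>gene`` TSV."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        fields = first.rstrip("\n").split("\t")
        is_gmt = len(fields) > 2 or path_suffix_gmt(path)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if is_gmt:
                name, members = parts[0], parts[2:] if len(parts) > 2 else []
                sets.setdefault(name, set()).update(m for m in members if m)
            else:
                sets.setdefault(parts[0], set()).add(parts[1])
    return [GeneSet(name, frozenset(members)) for name, members in sets.items()]


def path_suffix_gmt(path) -> bool:
    return str(path).lower().endswith(".gmt")
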