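"""Panels of conserved non-coding elements around genes, and panel enrichment.

For each gene, the k nearest conserved elements (by midpoint distance on
the same chromosome, expanding in both directions) form its panel.  The
scan's accelerated elements are then tested for concentration in the panels
of a target gene set against a control set with a hypergeometric tail.

Intervals follow the BED convention: 0-based, half-open; the gene center is
``floor((start + end) / 2)``; strand is ignored for distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import EnrichmentResult, hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed",
    "ElementPanel",
    "assign_elements",
    "dedupe_panels",
    "panel_set_enrichment",
    "PanelEnrichment",
]

_BED_COLS = ["chrom", "start", "end", "id", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (>= 4 columns: chrom, start, end, id)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, : min(6, frame.shape[1])]
    frame.columns = _BED_COLS[: frame.shape[1]]
    if "id" not in frame.columns:
        raise ValueError("BED file needs a name column (4th field)")
    if (frame["start"] >= frame["end"]).any():
        bad = frame.loc[frame["start"] >= frame["end"], "id"].iloc[0]
        raise ValueError(f"interval {bad!r} has start >= end")
    if frame["id"].duplicated().any():
        dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate interval id {dup!r}")
    return frame


def _midpoints(frame: pd.DataFrame) -> pd.Series:
    return (frame["start"] + frame["end"]) // 2


@dataclass
class ElementPanel:
    """The k elements nearest one gene, with signed midpoint distances."""

    gene_id: str
    elements: pd.DataFrame  # columns: element_id, distance; |distance| nondecreasing

    @property
    def element_ids(self) -> list[str]:
        return list(self.elements["element_id"])


def assign_elements(
    genes: pd.DataFrame,
    elements: pd.DataFrame,
    k: int = 200,
) -> dict[str, ElementPanel]:
    """Per gene, the k same-chromosome elements with smallest |midpoint distance|.

    Ties in |distance| are broken by the smaller element start coordinate.
    Genes on chromosomes absent from the element file get empty panels with
    a warning; so do genes with fewer than k available elements.
    """
    panels: dict[str, ElementPanel] = {}
    el_by_chrom = {c: sub for c, sub in elements.groupby("chrom")}
    for _, gene in genes.iterrows():
        gid = gene["id"]
        sub = el_by_chrom.get(gene["chrom"])
        if sub is None:
            logger.warning("gene %s: chromosome %s has no elements", gid, gene["chrom"])
            panels[gid] = ElementPanel(
                gid, pd.DataFrame(columns=["element_id", "distance"])
            )
            continue
        gmid = (int(gene["start"]) + int(gene["end"])) // 2
        dist = _midpoints(sub).to_numpy() - gmid
        order = np.lexsort((sub["start"].to_numpy(), np.abs(dist)))
        if len(order) < k:
            logger.warning(
                "gene %s: only %d elements available (k=%d)", gid, len(order), k
            )
        take = order[:k]
        panels[gid] = ElementPanel(
            gid,
            pd.DataFrame(
                {
                    "element_id": sub["id"].to_numpy()[take],
                    "distance": dist[take],
                }
            ),
        )
    return panels


def dedupe_panels(
    *panel_groups: Mapping[str, ElementPanel],
) -> list[Mapping[str, ElementPanel]]:
    """Assign each element to its single closest gene across all panels.

    Prevents double counting in enrichment margins when an element is within
    k-nearest of several genes.  Ties go to the lexicographically smaller
    gene id.
    """
    best: dict[str, tuple[int, str, int]] = {}
    for gi, group in enumerate(panel_groups):
        for gid, panel in group.items():
            for eid, d in zip(panel.elements["element_id"], panel.elements["distance"]):
                key = (abs(int(d)), str(gid), gi)
                if eid not in best or key < best[eid][:3]:
                    best[eid] = key
    out = []
    for gi, group in enumerate(panel_groups):
        new_group = {}
        for gid, panel in group.items():
            keep = [
                eid
                for eid in panel.elements["element_id"]
                if best[eid][1] == str(gid) and best[eid][2] == gi
            ]
            mask = panel.elements["element_id"].isin(keep)
            new_group[gid] = ElementPanel(gid, panel.elements.loc[mask].reset_index(drop=True))
        out.append(new_group)
    return out


@dataclass(frozen=True)
class PanelEnrichment:
    element_level: EnrichmentResult
    gene_level: EnrichmentResult
    no_hits: bool


def panel_set_enrichment(
    scan_calls: Mapping[str, bool] | pd.Series,
    eye_panels: Mapping[str, ElementPanel],
    other_panels: Mapping[str, ElementPanel],
    name: str = "eye",
) -> PanelEnrichment:
    """Are accelerated elements concentrated in the target (eye) panels?

    ``scan_calls`` maps element ids to accelerated-or-not at the chosen FDR.
    Panels must already be disjoint in element ids (see :func:`dedupe_panels`).
    Element-level margins: N = scored panel elements, K = those in eye
    panels, n = accelerated, k = accelerated in eye panels.  Gene-level:
    the same over genes owning at least one accelerated element.
    """
    calls = pd.Series(scan_calls, dtype=bool)
    eye_ids = {e for p in eye_panels.values() for e in p.element_ids}
    other_ids = {e for p in other_panels.values() for e in p.element_ids}
    overlap = eye_ids & other_ids
    if overlap:
        raise ValueError(
            f"panels share {len(overlap)} element(s); resolve with dedupe_panels first"
        )
    scored = (eye_ids | other_ids) & set(calls.index)
    eye_scored = eye_ids & scored
    hits = {e for e in scored if calls[e]}
    no_hits = len(hits) == 0
    if no_hits:
        element_level = EnrichmentResult(
            name=name, N=len(scored), K=len(eye_scored), n=0, k=0, fold=0.0, p=1.0
        )
    else:
        element_level = hypergeom_tail(
            len(scored), len(eye_scored), len(hits), len(hits & eye_ids), name
        )

    owner: dict[str, str] = {}
    gene_group: dict[str, str] = {}
    for label, group in (("eye", eye_panels), ("other", other_panels)):
        for gid, panel in group.items():
            gene_group[gid] = label
            for eid in panel.element_ids:
                owner[eid] = gid
    genes_with_scored = {owner[e] for e in scored}
    eye_genes = {g for g in genes_with_scored if gene_group[g] == "eye"}
    hit_genes = {owner[e] for e in hits}
    if no_hits:
        gene_level = EnrichmentResult(
            name=name, N=len(genes_with_scored), K=len(eye_genes), n=0, k=0,
            fold=0.0, p=1.0,
        )
    else:
        gene_level = hypergeom_tail(
            len(genes_with_scored),
            len(eye_genes),
            len(hit_genes),
            len(hit_genes & eye_genes),
            name,
        )
    return PanelEnrichment(element_level=element_level, gene_level=gene_level, no_hits=no_hits)
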