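"""Relative evolutionary rates by projection onto the average tree.

The observed branch lengths of one element form a vector ``g`` over the
master branches it covers; the genome-wide average tree supplies the
expected vector ``A`` over the same branches.  The relative evolutionary
rate (RER) is the residual after projecting ``g`` onto ``A``::

    beta = (g . A) / (A . A)        # per-element scale
    RER  = g - beta * A             # signed, orthogonal to A

so an RER of zero on a branch means the element diverged exactly as much as
expected there given its overall rate.  Elements missing taxa contribute
merged branch *paths*: the observed path total is compared against the sum
of the member branches' averages, and the residual is attributed to the
deepest member branch of the path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import ElementTree, MasterTree, Rejection

logger = logging.getLogger(__name__)

__all__ = [
    "FilterCriteria",
    "RateMatrix",
    "RERMatrix",
    "filter_trees",
    "estimate_average_tree",
    "compute_rer",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Element-tree retention rules.

    Defaults mirror the published analysis: at least 10 species, at least
    two of them foreground, and rejection when 80% or more of the species
    present have zero-length terminal branches.
    """

    min_species: int = 10
    min_foreground: int = 2
    zero_fraction: float = 0.80

    def __post_init__(self):
        if not (0 < self.zero_fraction <= 1):
            raise ValueError("zero_fraction must be in (0, 1]")
        if self.min_species < 1 or self.min_foreground < 1:
            raise ValueError("species counts must be >= 1")


def filter_trees(
    trees: Sequence[ElementTree],
    foreground: Iterable[str],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[ElementTree], list[Rejection]]:
    """Apply the retention rules, returning retained trees and a rejection log."""
    if not trees:
        raise ValueError("no element trees supplied")
    fg = frozenset(foreground)
    retained: list[ElementTree] = []
    log: list[Rejection] = []
    for tree in trees:
        n = tree.n_taxa
        n_fg = len(tree.taxa & fg)
        if n < criteria.min_species:
            log.append(
                Rejection(tree.element_id, "min_species", f"{n} < {criteria.min_species}")
            )
            continue
        if n_fg < criteria.min_foreground:
            log.append(
                Rejection(
                    tree.element_id,
                    "min_foreground",
                    f"{n_fg} < {criteria.min_foreground}",
                )
            )
            continue
        zfrac = tree.zero_terminal_fraction()
        if zfrac >= criteria.zero_fraction:
            log.append(
                Rejection(
                    tree.element_id,
                    "zero_fraction",
                    f"{zfrac:.3f} >= {criteria.zero_fraction}",
                )
            )
            continue
        retained.append(tree)
    return retained, log


class RateMatrix:
    """Raw branch lengths, elements x master branches.

    Each element branch's observed length is stored on the *representative*
    master branch of the path it spans (the deepest member); the remaining
    path members are missing for that element.  ``merged`` records the
    non-trivial paths so expectations can be formed as path sums.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        merged: dict[str, dict[str, tuple[str, ...]]],
        master: MasterTree,
    ):
        self.values = values
        self.merged = merged
        self.master = master

    @classmethod
    def from_trees(cls, trees: Sequence[ElementTree], master: MasterTree) -> "RateMatrix":
        if not trees:
            raise ValueError("no element trees supplied")
        ids = [t.element_id for t in trees]
        arr = np.full((len(trees), len(master.branch_ids)), np.nan)
        col = {b: j for j, b in enumerate(master.branch_ids)}
        merged: dict[str, dict[str, tuple[str, ...]]] = {}
        for i, tree in enumerate(trees):
            paths = master.branch_paths(tree.taxa)
            el_merged: dict[str, tuple[str, ...]] = {}
            for key, members in paths.items():
                rep = members[0]
                arr[i, col[rep]] = tree.lengths[key]
                if len(members) > 1:
                    el_merged[rep] = members
            if el_merged:
                merged[tree.element_id] = el_merged
        values = pd.DataFrame(arr, index=ids, columns=list(master.branch_ids))
        return cls(values, merged, master)

    @property
    def element_ids(self) -> list[str]:
        return list(self.values.index)

    def singleton_mask(self) -> np.ndarray:
        """Cells observed as un-merged single branches (usable for averaging)."""
        mask = self.values.notna().to_numpy()
        col = {b: j for j, b in enumerate(self.values.columns)}
        row = {e: i for i, e in enumerate(self.values.index)}
        for eid, paths in self.merged.items():
            for rep in paths:
                mask[row[eid], col[rep]] = False
        return mask

    def expected_matrix(self, avg: np.ndarray) -> np.ndarray:
        """Per-cell expectation: branch average, or path sum on merged reps."""
        present = self.values.notna().to_numpy()
        E = np.where(present, avg[None, :], np.nan)
        col = {b: j for j, b in enumerate(self.values.columns)}
        row = {e: i for i, e in enumerate(self.values.index)}
        for eid, paths in self.merged.items():
            i = row[eid]
            for rep, members in paths.items():
                E[i, col[rep]] = sum(avg[col[m]] for m in members)
        return E

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g", index_label="element_id")


def estimate_average_tree(
    matrix: RateMatrix,
    max_iter: int = 10,
    tol: float = 1e-6,
) -> MasterTree:
    """Estimate per-branch expected divergence from the rate matrix.

    Pass 1 averages raw lengths over elements observing each branch as a
    singleton path.  Pass 2 rescales each element by its projection
    coefficient onto the pass-1 averages before re-averaging, so that fast-
    or slow-evolving elements contribute comparably; passes repeat to a
    fixed point (relative change < ``tol``).
    """
    V = matrix.values.to_numpy()
    if V.shape[0] < 2:
        raise ValueError("need at least two elements to average")
    singleton = matrix.singleton_mask()
    n_obs = singleton.sum(axis=0)
    if np.any(n_obs == 0):
        bad = [b for b, n in zip(matrix.values.columns, n_obs) if n == 0]
        raise ValueError(f"master branches never observed un-merged: {bad}")

    with np.errstate(invalid="ignore"):
        avg = np.nansum(np.where(singleton, V, 0.0), axis=0) / n_obs

    for _ in range(max_iter):
        E = matrix.expected_matrix(avg)
        num = np.nansum(np.where(np.isnan(E), 0.0, V * E), axis=1)
        den = np.nansum(np.where(np.isnan(E), 0.0, E * E), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = num / den
        usable = np.isfinite(s) & (s > 0)
        scaled = np.where(usable[:, None], V / np.where(usable, s, 1.0)[:, None], np.nan)
        obs = singleton & usable[:, None]
        counts = obs.sum(axis=0)
        if np.any(counts == 0):
            break  # degenerate rescaling; keep the previous estimate
        new_avg = np.nansum(np.where(obs, scaled, 0.0), axis=0) / counts
        rel = np.max(np.abs(new_avg - avg) / np.maximum(np.abs(avg), 1e-300))
        avg = new_avg
        if rel < tol:
            break
    return matrix.master.with_avg_lengths(dict(zip(matrix.values.columns, avg)))


@dataclass
class RERMatrix:
    """Projection residuals per element x master branch.

    ``values`` holds the signed relative rates (missing where the element
    lacks the branch); ``beta`` the per-element projection coefficient onto
    the average tree; ``scaled`` whether rows were divided by their within-
    element standard deviation.
    """

    values: pd.DataFrame
    beta: pd.Series
    scaled: bool
    master: MasterTree
    merged: dict[str, dict[str, tuple[str, ...]]]

    def terminal_frame(self) -> pd.DataFrame:
        return self.values[list(self.master.terminal_ids)]

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g", index_label="element_id")
        if sidecar_path is not None:
            meta = {
                "scaled": self.scaled,
                "beta": {k: float(v) for k, v in self.beta.items()},
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)


def compute_rer(
    matrix: RateMatrix,
    master: MasterTree,
    scale: bool | str = False,
) -> RERMatrix:
    """Project each element's branch lengths onto the average tree.

    ``scale`` selects an optional standardization of the residuals:
    ``False``/``"none"`` leaves them raw (default; orthogonal to the
    expectations); ``True``/``"element"`` divides each element's residuals
    by their within-element standard deviation; ``"branch"`` z-scores each
    branch across elements, which equalizes the residual spread that
    otherwise grows with a branch's expected divergence.
    """
    if master.avg_lengths is None:
        raise ValueError("master tree has no average branch lengths")
    avg = np.array([master.avg_lengths[b] for b in matrix.values.columns])
    V = matrix.values.to_numpy()
    E = matrix.expected_matrix(avg)
    num = np.nansum(np.where(np.isnan(E), 0.0, V * E), axis=1)
    den = np.nansum(np.where(np.isnan(E), 0.0, E * E), axis=1)
    if np.any(den == 0):
        bad = [e for e, d in zip(matrix.values.index, den) if d == 0]
        raise ValueError(f"degenerate expectations (A.A = 0) for elements: {bad}")
    beta = num / den
    R = V - beta[:, None] * E
    mode = {False: "none", True: "element"}.get(scale, scale)
    if mode not in ("none", "element", "branch"):
        raise ValueError(f"unknown scale mode {scale!r}")
    if mode == "element":
        with np.errstate(invalid="ignore"):
            sd = np.sqrt(np.nanvar(R, axis=1, ddof=1))
        ok = np.isfinite(sd) & (sd > 0)
        R = np.where(ok[:, None], R / np.where(ok, sd, 1.0)[:, None], R)
    elif mode == "branch":
        with np.errstate(invalid="ignore"):
            mu = np.nanmean(R, axis=0)
            sd = np.sqrt(np.nanvar(R, axis=0, ddof=1))
        ok = np.isfinite(sd) & (sd > 0)
        R = np.where(ok[None, :], (R - mu[None, :]) / np.where(ok, sd, 1.0)[None, :], R)
    values = pd.DataFrame(R, index=matrix.values.index, columns=matrix.values.columns)
    return RERMatrix(
        values=values,
        beta=pd.Series(beta, index=matrix.values.index, name="beta"),
        scaled=mode != "none",
        master=master,
        merged=matrix.merged,
    )
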