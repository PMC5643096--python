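"""Convergent rate-shift scan: Mann-Whitney statistics and permutation FDR.

Each element's relative rates are split into *foreground* branches (those
leading to the convergent lineages, by default their terminal branches) and
the remaining *background* branches.  A Mann-Whitney U test asks whether
foreground rates are systematically shifted; the normalized statistic
``auc = U / (n_fg * n_bg)`` is the probability that a random foreground
branch out-rates a random background branch, so values above 0.5 indicate
acceleration.

Significance is calibrated empirically: null datasets are formed by drawing
pseudo-foreground species sets uniformly at random (one set per dataset,
applied to every element, which preserves cross-element dependence), and
q-values are the expected number of null discoveries at a p-value cutoff
divided by the observed number, monotonized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rer import RERMatrix
from .trees import MasterTree

logger = logging.getLogger(__name__)

__all__ = [
    "ForegroundSpec",
    "PermutationPlan",
    "ScanResult",
    "ConvergentRateScan",
    "ConvergentScanResults",
    "score_element",
    "scan_all",
    "permutation_qvalues",
]

#: exact Mann-Whitney enumeration is used up to this product of group sizes
EXACT_LIMIT = 400

_COUNT_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _u_counts(m: int, n: int) -> np.ndarray:
    """Number of rank assignments with each U value, for tie-free data.

    ``counts[u]`` is the number of ways to choose which ``m`` of the
    ``m + n`` ranks are foreground such that the U statistic equals ``u``;
    computed by the classic recurrence
    ``N(m, n, u) = N(m, n-1, u) + N(m-1, n, u - n)``.
    """
    if m > n:  # symmetry keeps the cache small
        m, n = n, m
    key = (m, n)
    cached = _COUNT_CACHE.get(key)
    if cached is not None:
        return cached
    if m == 0:
        out = np.array([1.0])
    else:
        a = _u_counts(m, n - 1) if n > 1 else None
        b = _u_counts(m - 1, n)
        out = np.zeros(m * n + 1)
        if n > 1:
            out[: a.size] += a
        else:  # n == 1: N(m, 0, u) = 1 at u = 0
            out[0] += 1.0
        out[n : n + b.size] += b
    _COUNT_CACHE[key] = out
    return out


def _exact_tails(m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(P(U <= u), P(U >= u)) for u = 0..m*n under the tie-free null."""
    counts = _u_counts(m, n)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    return cdf, sf


@dataclass(frozen=True)
class ForegroundSpec:
    """Which branches count as foreground.

    ``policy='terminal'`` uses only the terminal branches of the foreground
    species (appropriate when the convergent lineages are phylogenetically
    independent); ``'terminal+internal'`` additionally includes internal
    branches whose entire clade is foreground.
    """

    species: frozenset
    policy: str = "terminal"

    def __post_init__(self):
        object.__setattr__(self, "species", frozenset(self.species))
        if len(self.species) < 2:
            raise ValueError("need at least two foreground species")
        if self.policy not in ("terminal", "terminal+internal"):
            raise ValueError(f"unknown branch policy {self.policy!r}")

    def branch_ids(self, master: MasterTree) -> list[str]:
        unknown = self.species - set(master.taxa)
        if unknown:
            raise ValueError(f"foreground species not in master tree: {sorted(unknown)}")
        ids = [t for t in master.terminal_ids if t in self.species]
        if self.policy == "terminal+internal":
            ids += [
                b for b in master.internal_ids if master.clade_of(b) <= self.species
            ]
        return ids


@dataclass
class PermutationPlan:
    """Seeded pseudo-foreground draws for the empirical null."""

    n_perm: int = 10000
    seed: int | None = None
    sets: list[tuple[str, ...]] = field(default_factory=list)

    @classmethod
    def generate(
        cls,
        n_perm: int,
        seed: int | None,
        eligible: Sequence[str],
        size: int,
    ) -> "PermutationPlan":
        if n_perm < 100:
            warnings.warn(
                f"n_perm={n_perm} < 100: q-value estimates will be unstable",
                stacklevel=2,
            )
        eligible = sorted(eligible)
        if size > len(eligible):
            raise ValueError("fewer eligible taxa than foreground size")
        rng = np.random.default_rng(seed)
        sets = [
            tuple(rng.choice(eligible, size=size, replace=False))
            for _ in range(n_perm)
        ]
        return cls(n_perm=n_perm, seed=seed, sets=sets)


@dataclass(frozen=True)
class ScanResult:
    """Per-element scan statistics (q-values filled in after permutation)."""

    element_id: str
    n_fg: int
    n_bg: int
    U: float
    auc: float
    p: float
    p_accel: float
    q_accel: float = np.nan
    q_decel: float = np.nan
    label: str = "neither"


class _RankedMatrix:
    """Within-row ranks of an RER matrix, reused across permutations."""

    def __init__(self, values: pd.DataFrame):
        self.index = values.index
        self.columns = list(values.columns)
        M = values.to_numpy(dtype=float)
        self.present = ~np.isnan(M)
        self.n_present = self.present.sum(axis=1)
        self.ranks0 = np.zeros_like(M)  # zero-filled ranks for fast sums
        self.tie_term = np.zeros(M.shape[0])
        self.has_ties = np.zeros(M.shape[0], dtype=bool)
        for i in range(M.shape[0]):
            v = M[i, self.present[i]]
            if v.size == 0:
                continue
            r = stats.rankdata(v)
            self.ranks0[i, self.present[i]] = r
            _, counts = np.unique(v, return_counts=True)
            if np.any(counts > 1):
                self.has_ties[i] = True
                t = counts[counts > 1].astype(float)
                self.tie_term[i] = np.sum(t**3 - t)

    def col_indices(self, branch_ids: Iterable[str]) -> np.ndarray:
        lookup = {b: j for j, b in enumerate(self.columns)}
        return np.array([lookup[b] for b in branch_ids if b in lookup], dtype=int)

    def stats_for(self, fg_cols: np.ndarray) -> dict[str, np.ndarray]:
        """U, auc and p-values for every row against one foreground set."""
        n_rows = self.ranks0.shape[0]
        if fg_cols.size == 0:
            nan = np.full(n_rows, np.nan)
            return {
                "n_fg": np.zeros(n_rows, dtype=int), "n_bg": self.n_present.astype(int),
                "U": nan, "auc": nan, "p": nan, "p_accel": nan,
                "valid": np.zeros(n_rows, dtype=bool),
            }
        n_fg = self.present[:, fg_cols].sum(axis=1)
        n_bg = self.n_present - n_fg
        rank_sum = self.ranks0[:, fg_cols].sum(axis=1)
        U = rank_sum - n_fg * (n_fg + 1) / 2.0
        return _tails_from_U(self, U, n_fg, n_bg)


def score_element(
    rer_row: Mapping[str, float] | pd.Series,
    fg: ForegroundSpec,
    master: MasterTree,
) -> ScanResult:
    """Mann-Whitney scan statistics for a single element.

    ``rer_row`` maps branch ids to relative rates (missing branches absent
    or NaN).  Requires at least one foreground and one background branch.
    """
    row = pd.Series(rer_row, dtype=float)
    ranked = _RankedMatrix(row.to_frame().T)
    out = ranked.stats_for(ranked.col_indices(fg.branch_ids(master)))
    if not out["valid"][0]:
        raise ValueError("element has no usable foreground/background split")
    return ScanResult(
        element_id=str(row.name) if row.name is not None else "",
        n_fg=int(out["n_fg"][0]),
        n_bg=int(out["n_bg"][0]),
        U=float(out["U"][0]),
        auc=float(out["auc"][0]),
        p=float(out["p"][0]),
        p_accel=float(out["p_accel"][0]),
    )


def _observed_frame(ranked: _RankedMatrix, fg_cols: np.ndarray) -> pd.DataFrame:
    out = ranked.stats_for(fg_cols)
    frame = pd.DataFrame(
        {
            "n_fg": out["n_fg"],
            "n_bg": out["n_bg"],
            "U": out["U"],
            "auc": out["auc"],
            "p": out["p"],
            "p_accel": out["p_accel"],
        },
        index=ranked.index,
    )
    skipped = ~out["valid"]
    if np.any(skipped):
        for eid in frame.index[skipped]:
            logger.info("element %s skipped: no foreground/background split", eid)
        frame = frame.loc[~skipped]
    return frame.sort_index()


def scan_all(rer: RERMatrix, fg: ForegroundSpec) -> pd.DataFrame:
    """Score every element; one row per element, ordered by element id."""
    if rer.values.empty:
        raise ValueError("empty RER matrix")
    ranked = _RankedMatrix(rer.values)
    return _observed_frame(ranked, ranked.col_indices(fg.branch_ids(rer.master)))


def _empirical_q(
    obs_p: np.ndarray,
    null_p_sorted: np.ndarray,
    n_perm: int,
) -> np.ndarray:
    """q(p) = mean null discoveries at p / observed discoveries at p, monotonized."""
    order = np.argsort(obs_p, kind="stable")
    sorted_p = obs_p[order]
    # with tied p's, every tied value shares the count of all values <= it
    n_obs_le = np.searchsorted(sorted_p, sorted_p, side="right").astype(float)
    n_null_le = np.searchsorted(null_p_sorted, sorted_p, side="right") / n_perm
    q = np.minimum(1.0, n_null_le / n_obs_le)
    q = np.minimum.accumulate(q[::-1])[::-1]  # running min from largest p down
    out = np.empty_like(q)
    out[order] = q
    return out


def permutation_qvalues(
    observed: pd.DataFrame,
    rer: RERMatrix,
    plan: PermutationPlan,
    fg: ForegroundSpec,
    permute: str = "dataset",
) -> pd.DataFrame:
    """Empirical q-values for each direction from pseudo-foreground nulls.

    ``permute='dataset'`` applies one pseudo-foreground species set to all
    elements per null dataset; ``'element'`` draws an independent set of
    foreground branches per element (within each element's present
    branches), breaking cross-element dependence.
    """
    ranked = _RankedMatrix(rer.values)
    size = len(fg.species)
    null_accel: list[np.ndarray] = []
    null_decel: list[np.ndarray] = []
    rng = np.random.default_rng(plan.seed)
    for k in range(plan.n_perm):
        if permute == "dataset":
            pseudo = plan.sets[k]
            cols = ranked.col_indices(pseudo)
            out = ranked.stats_for(cols)
        elif permute == "element":
            out = _per_element_null(ranked, size, rng)
        else:
            raise ValueError(f"unknown permute mode {permute!r}")
        valid = out["valid"]
        p = out["p"][valid]
        auc = out["auc"][valid]
        null_accel.append(p[auc > 0.5])
        null_decel.append(p[auc < 0.5])

    na = np.sort(np.concatenate(null_accel)) if null_accel else np.array([])
    nd = np.sort(np.concatenate(null_decel)) if null_decel else np.array([])

    q_accel = np.full(len(observed), np.nan)
    q_decel = np.full(len(observed), np.nan)
    auc = observed["auc"].to_numpy()
    p = observed["p"].to_numpy()
    accel = auc > 0.5
    decel = auc < 0.5
    if np.any(accel):
        q_accel[accel] = _empirical_q(p[accel], na, plan.n_perm)
    if np.any(decel):
        q_decel[decel] = _empirical_q(p[decel], nd, plan.n_perm)
    out = observed.copy()
    out["q_accel"] = q_accel
    out["q_decel"] = q_decel
    return out


def _per_element_null(
    ranked: _RankedMatrix, size: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One null dataset with per-element independent foreground branches."""
    n_rows, n_cols = ranked.ranks0.shape
    noise = rng.random((n_rows, n_cols))
    noise[~ranked.present] = np.inf
    # the `size` smallest noise values among present columns become foreground
    kth = np.argsort(noise, axis=1)[:, :size]
    fg_mask = np.zeros_like(ranked.present)
    rows = np.repeat(np.arange(n_rows), size)
    fg_mask[rows, kth.ravel()] = True
    fg_mask &= ranked.present

    n_fg = fg_mask.sum(axis=1)
    n_bg = ranked.n_present - n_fg
    rank_sum = np.where(fg_mask, ranked.ranks0, 0.0).sum(axis=1)
    U = rank_sum - n_fg * (n_fg + 1) / 2.0
    return _tails_from_U(ranked, U, n_fg, n_bg)


def _tails_from_U(
    ranked: _RankedMatrix, U: np.ndarray, n_fg: np.ndarray, n_bg: np.ndarray
) -> dict[str, np.ndarray]:
    n_rows = U.size
    valid = (n_fg > 0) & (n_bg > 0)
    mn = np.where(valid, n_fg * n_bg, 1)
    auc = np.where(valid, U / mn, np.nan)
    p = np.full(n_rows, np.nan)
    p_acc = np.full(n_rows, np.nan)
    exact = valid & ~ranked.has_ties & (n_fg * n_bg <= EXACT_LIMIT)
    keys = n_fg * 10000 + n_bg
    for key in np.unique(keys[exact]):
        sel = exact & (keys == key)
        m, n = int(key // 10000), int(key % 10000)
        cdf, sf = _exact_tails(m, n)
        u = np.rint(U[sel]).astype(int)
        p[sel] = np.minimum(1.0, 2.0 * np.minimum(cdf[u], sf[u]))
        p_acc[sel] = sf[u]
    approx = valid & ~exact
    if np.any(approx):
        mN = ranked.n_present[approx].astype(float)
        mu = n_fg[approx] * n_bg[approx] / 2.0
        var = (
            n_fg[approx] * n_bg[approx] / 12.0
            * ((mN + 1.0) - ranked.tie_term[approx] / (mN * (mN - 1.0)))
        )
        sd = np.sqrt(np.maximum(var, 0.0))
        diff = U[approx] - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (diff - 0.5 * np.sign(diff)) / sd
            z_acc = (diff - 0.5) / sd
        p[approx] = np.where(sd > 0, np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z))), 1.0)
        p_acc[approx] = np.where(sd > 0, stats.norm.sf(z_acc), 0.5)
    return {
        "n_fg": n_fg.astype(int), "n_bg": n_bg.astype(int),
        "U": U, "auc": auc, "p": p, "p_accel": p_acc, "valid": valid,
    }


class ConvergentRateScan:
    """Model: convergent rate-shift scan of an RER matrix.

    Parameters
    ----------
    rer : RERMatrix
        Relative rates, elements x master branches.
    foreground : ForegroundSpec or iterable of str
        The convergent species (or a full spec with a branch policy).
    direction_threshold : float
        Minimum ``auc`` for an accelerated call (``1 - threshold`` maximum
        for decelerated); 0.5 makes it a pure direction rule.
    fdr : float
        q-value cutoff for calls (default 0.15).

    Examples
    --------
    >>> model = ConvergentRateScan(rer, {"sp01", "sp07", "sp19", "sp30"})
    >>> res = model.fit(n_perm=1000, seed=17)
    >>> print(res.summary())
    """

    def __init__(
        self,
        rer: RERMatrix,
        foreground: ForegroundSpec | Iterable[str],
        direction_threshold: float = 0.5,
        fdr: float = 0.15,
    ):
        if not isinstance(foreground, ForegroundSpec):
            foreground = ForegroundSpec(species=frozenset(foreground))
        self.rer = rer
        self.foreground = foreground
        self.direction_threshold = direction_threshold
        self.fdr = fdr

    @classmethod
    def from_trees(
        cls,
        trees,
        master: MasterTree,
        foreground: ForegroundSpec | Iterable[str],
        criteria=None,
        scale: bool = False,
        **kwargs,
    ) -> "ConvergentRateScan":
        """Filter trees, estimate the average tree, compute RERs, build the model."""
        from .rer import FilterCriteria, RateMatrix, compute_rer, estimate_average_tree
        from .rer import filter_trees

        if not isinstance(foreground, ForegroundSpec):
            foreground = ForegroundSpec(species=frozenset(foreground))
        if criteria is None:
            criteria = FilterCriteria()
        retained, log = filter_trees(trees, foreground.species, criteria)
        if not retained:
            raise ValueError("no trees survive filtering")
        matrix = RateMatrix.from_trees(retained, master)
        avg_master = estimate_average_tree(matrix)
        rer = compute_rer(matrix, avg_master, scale=scale)
        model = cls(rer, foreground, **kwargs)
        model.filter_log = log
        return model

    def fit(
        self,
        n_perm: int = 10000,
        seed: int | None = None,
        permute: str = "dataset",
    ) -> "ConvergentScanResults":
        """Score all elements and estimate permutation q-values."""
        observed = scan_all(self.rer, self.foreground)
        eligible = [
            t
            for t in self.rer.master.terminal_ids
            if self.rer.values[t].notna().any()
        ]
        plan = PermutationPlan.generate(
            n_perm, seed, eligible, len(self.foreground.species)
        )
        frame = permutation_qvalues(observed, self.rer, plan, self.foreground, permute)
        thr = self.direction_threshold
        label = np.where(
            (frame["auc"] >= thr) & (frame["q_accel"] <= self.fdr),
            "accelerated",
            np.where(
                (frame["auc"] <= 1 - thr) & (frame["q_decel"] <= self.fdr),
                "decelerated",
                "neither",
            ),
        )
        frame["label"] = label
        return ConvergentScanResults(self, frame, plan)


class ConvergentScanResults:
    """Fitted scan: per-element statistics, q-values and calls."""

    def __init__(self, model: ConvergentRateScan, frame: pd.DataFrame, plan: PermutationPlan):
        self.model = model
        self.frame = frame
        self.plan = plan

    @property
    def accelerated(self) -> pd.DataFrame:
        return self.frame[self.frame["label"] == "accelerated"]

    @property
    def decelerated(self) -> pd.DataFrame:
        return self.frame[self.frame["label"] == "decelerated"]

    def pvalues(self, direction: str = "two-sided") -> pd.Series:
        if direction == "accel":
            return self.frame["p_accel"]
        return self.frame["p"]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.10g", index_label="element_id")

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Convergent rate-shift scan",
            "==========================",
            f"elements scored        {len(f)}",
            f"foreground species     {', '.join(sorted(self.model.foreground.species))}",
            f"branch policy          {self.model.foreground.policy}",
            f"permutations           {self.plan.n_perm} (seed {self.plan.seed})",
            f"direction threshold    auc >= {self.model.direction_threshold}",
            f"FDR cutoff             {self.model.fdr}",
            f"accelerated calls      {int((f['label'] == 'accelerated').sum())}",
            f"decelerated calls      {int((f['label'] == 'decelerated').sum())}",
        ]
        top = f.nsmallest(min(5, len(f)), "p")
        lines.append("top elements by p:")
        for eid, row in top.iterrows():
            lines.append(
                f"  {eid}  auc={row['auc']:.3f}  p={row['p']:.3g}  label={row['label']}"
            )
        return "\n".join(lines)
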