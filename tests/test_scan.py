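"""Mann-Whitney scan statistics, exact p oracle, and permutation q-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from convergescan.rer import RERMatrix
from convergescan.scan import (
    ConvergentRateScan,
    ForegroundSpec,
    PermutationPlan,
    _empirical_q,
    permutation_qvalues,
    scan_all,
    score_element,
)
from convergescan.simulate import SimulationConfig, simulate_element_trees


def brute_force_two_sided(fg_vals, bg_vals):
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments."""
    pooled = list(fg_vals) + list(bg_vals)
    m = len(fg_vals)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs_u = sum(ranks[v] for v in fg_vals) - m * (m + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), m):
        u = sum(sorted(ranks.values())[i] for i in combo) - m * (m + 1) / 2
        us.append(u)
    us = np.array(us)
    lo = np.mean(us <= obs_u)
    hi = np.mean(us >= obs_u)
    return min(1.0, 2 * min(lo, hi)), np.mean(us >= obs_u)


def rer_from_frame(frame, master):
    return RERMatrix(
        values=frame, beta=pd.Series(dtype=float), scaled=False, master=master,
        merged={},
    )


class TestScoreElement:
    def test_foreground_above_background(self, master4):
        row = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}, name="e1")
        res = score_element(row, ForegroundSpec(frozenset("CD")), master4)
        assert (res.U, res.auc) == (4.0, 1.0)
        assert res.p == pytest.approx(1 / 3)
        assert res.p_accel == pytest.approx(1 / 6)

    def test_foreground_below_background(self, master4):
        row = pd.Series({"A": 3.0, "B": 4.0, "C": 1.0, "D": 2.0}, name="e1")
        res = score_element(row, ForegroundSpec(frozenset("CD")), master4)
        assert (res.U, res.auc) == (0.0, 0.0)
        assert res.p == pytest.approx(1 / 3)

    def test_complete_ties(self, master4):
        row = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0}, name="e1")
        res = score_element(row, ForegroundSpec(frozenset("CD")), master4)
        assert (res.U, res.auc, res.p) == (2.0, 0.5, 1.0)

    def test_no_foreground_branch_errors(self, master4):
        row = pd.Series({"A": 1.0, "B": 2.0}, name="e1")
        with pytest.raises(ValueError):
            score_element(row, ForegroundSpec(frozenset("CD")), master4)

    def test_internal_branch_policy(self, master4):
        row = pd.Series(
            {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "anc02": 5.0}, name="e1"
        )
        spec = ForegroundSpec(frozenset("CD"), policy="terminal+internal")
        assert set(spec.branch_ids(master4)) == {"C", "D", "anc02"}
        res = score_element(row, spec, master4)
        assert res.n_fg == 3


class TestExactOracle:
    def test_matches_enumeration_for_all_small_splits(self):
        rng = np.random.default_rng(0)
        from convergescan.scan import _RankedMatrix

        for m in range(1, 7):
            for n in range(m, 37):
                if m * n > 36:
                    continue
                vals = rng.normal(size=m + n)
                while len(set(vals)) < len(vals):  # distinct values only
                    vals = rng.normal(size=m + n)
                expected_p, expected_one = brute_force_two_sided(vals[:m], vals[m:])
                frame = pd.DataFrame([vals], index=["e"],
                                     columns=[f"b{i}" for i in range(m + n)])
                ranked = _RankedMatrix(frame)
                out = ranked.stats_for(np.arange(m))
                assert out["p"][0] == pytest.approx(expected_p, abs=1e-12)
                assert out["p_accel"][0] == pytest.approx(expected_one, abs=1e-12)

    def test_auc_complementarity(self):
        rng = np.random.default_rng(1)
        from convergescan.scan import _RankedMatrix

        for _ in range(20):
            m, n = rng.integers(1, 8, size=2)
            vals = rng.normal(size=m + n)
            frame = pd.DataFrame([vals], columns=[f"b{i}" for i in range(m + n)])
            ranked = _RankedMatrix(frame)
            a1 = ranked.stats_for(np.arange(m))["auc"][0]
            a2 = ranked.stats_for(np.arange(m, m + n))["auc"][0]
            assert a1 + a2 == pytest.approx(1.0)


class TestScanAll:
    def test_ordering_and_constant_rows(self, master4):
        frame = pd.DataFrame(
            {
                "A": [1.0, 5.0], "B": [2.0, 5.0], "C": [3.0, 5.0], "D": [4.0, 5.0],
            },
            index=["e2", "e1"],
        )
        rer = rer_from_frame(frame, master4)
        out = scan_all(rer, ForegroundSpec(frozenset("CD")))
        assert list(out.index) == ["e1", "e2"]
        assert out.loc["e1", "p"] == 1.0  # constant row
        assert out.loc["e2", "p"] < out.loc["e1", "p"]

    def test_relabeling_invariance(self, master4):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=list("ABCD"),
            index=[f"e{i:02d}" for i in range(30)],
        )
        rer = rer_from_frame(frame, master4)
        p1 = scan_all(rer, ForegroundSpec(frozenset("CD")))["p"]
        relabeled = frame.rename(columns={"A": "C", "C": "A", "B": "D", "D": "B"})
        relabeled = relabeled[list("ABCD")]
        rer2 = rer_from_frame(relabeled, master4)
        p2 = scan_all(rer2, ForegroundSpec(frozenset("AB")))["p"]
        assert np.allclose(sorted(p1), sorted(p2))


class TestQValues:
    def test_hand_worked_example(self):
        obs = np.array([0.01, 0.02, 0.5, 0.8])
        null = np.sort([0.3, 0.6, 0.7, 0.9, 0.05, 0.4, 0.55, 0.95])
        q = _empirical_q(obs, null, n_perm=2)
        assert q == pytest.approx([0.0, 0.0, 0.5, 0.75])

    def test_null_equal_to_observed_gives_one(self):
        obs = np.array([0.01, 0.02, 0.5, 0.8])
        q = _empirical_q(obs, np.sort(obs), n_perm=1)
        assert q == pytest.approx([1.0, 1.0, 1.0, 1.0])

    def test_no_null_below_min_gives_zero(self):
        obs = np.array([0.001, 0.9])
        q = _empirical_q(obs, np.array([0.5, 0.95]), n_perm=1)
        assert q[0] == 0.0

    def test_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(3)
        obs = rng.uniform(size=50)
        null = np.sort(rng.uniform(size=200))
        q = _empirical_q(obs, null, n_perm=4)
        order = np.argsort(obs)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestPermutationPlan:
    def test_reproducible_and_well_formed(self):
        taxa = [f"sp{i}" for i in range(20)]
        a = PermutationPlan.generate(150, seed=9, eligible=taxa, size=4)
        b = PermutationPlan.generate(150, seed=9, eligible=taxa, size=4)
        assert a.sets == b.sets
        assert all(len(set(s)) == 4 and set(s) <= set(taxa) for s in a.sets)

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            PermutationPlan.generate(50, seed=0, eligible=list("abcdefgh"), size=2)


@pytest.fixture(scope="module")
def fitted():
    sim = simulate_element_trees(
        SimulationConfig(n_taxa=16, n_elements=150, min_species=8, seed=21)
    )
    model = ConvergentRateScan.from_trees(sim.trees, sim.master, sim.foreground)
    return sim, model, model.fit(n_perm=200, seed=5)


class TestModelFit:
    def test_determinism(self, fitted):
        sim, model, res = fitted
        res2 = model.fit(n_perm=200, seed=5)
        pd.testing.assert_frame_equal(res.frame, res2.frame)

    def test_planted_elements_rank_higher(self, fitted):
        sim, model, res = fitted
        truth = sim.truth.loc[res.frame.index, "accelerated"].to_numpy()
        mean_auc_planted = res.frame["auc"].to_numpy()[truth].mean()
        mean_auc_null = res.frame["auc"].to_numpy()[~truth].mean()
        assert mean_auc_planted > mean_auc_null

    def test_labels_consistent_with_direction(self, fitted):
        _, _, res = fitted
        acc = res.frame[res.frame["label"] == "accelerated"]
        dec = res.frame[res.frame["label"] == "decelerated"]
        assert (acc["auc"] >= 0.5).all()
        assert (acc["q_accel"] <= 0.15).all()
        assert (dec["auc"] < 0.5).all()

    def test_summary_mentions_key_settings(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "accelerated calls" in text and "200" in text

    def test_per_element_permutation_mode(self, fitted):
        sim, model, _ = fitted
        res = model.fit(n_perm=100, seed=5, permute="element")
        assert res.frame["q_accel"].dropna().between(0, 1).all()
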