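"""Filtering, average-tree estimation, and projection residuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_element
from convergescan.rer import (
    FilterCriteria,
    RateMatrix,
    RERMatrix,
    compute_rer,
    estimate_average_tree,
    filter_trees,
)
from convergescan.simulate import SimulationConfig, simulate_element_trees, simulate_master_tree
from convergescan.trees import ElementTree


@pytest.fixture(scope="module")
def master12():
    return simulate_master_tree(12, seed=7)


def element_with(master, n_taxa, n_zero_terminals=0, element_id="e"):
    taxa = sorted(master.taxa)[:n_taxa]
    lengths = {}
    zeroed = set(taxa[:n_zero_terminals])
    for key in master.branch_paths(taxa):
        if len(key) == 1 and next(iter(key)) in zeroed:
            lengths[key] = 0.0
        else:
            lengths[key] = 1.0
    return ElementTree(element_id=element_id, taxa=frozenset(taxa), lengths=lengths)


class TestFilter:
    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FilterCriteria(zero_fraction=0.0)
        with pytest.raises(ValueError):
            FilterCriteria(min_species=0)

    def test_rules_applied_in_order(self, master12):
        fg = set(sorted(master12.taxa)[:3])
        trees = [
            element_with(master12, 12, element_id="ok"),
            element_with(master12, 9, element_id="few_species"),
            element_with(master12, 10, n_zero_terminals=8, element_id="zeros"),
        ]
        # a tree with enough species but only one foreground taxon
        taxa_nofg = sorted(master12.taxa)[2:12]
        lengths = {k: 1.0 for k in master12.branch_paths(taxa_nofg)}
        trees.append(ElementTree("no_fg", frozenset(taxa_nofg), lengths))

        retained, log = filter_trees(trees, fg, FilterCriteria())
        assert [t.element_id for t in retained] == ["ok"]
        rules = {r.element_id: r.rule for r in log}
        assert rules == {
            "few_species": "min_species",
            "zeros": "zero_fraction",
            "no_fg": "min_foreground",
        }

    def test_boundary_zero_fraction(self, master12):
        # 8 of 10 terminal branches zero: 0.8 >= 0.80 is rejected,
        # 7 of 10 (0.7) is retained
        fg = set(sorted(master12.taxa)[:3])
        at = element_with(master12, 10, n_zero_terminals=8, element_id="at")
        below = element_with(master12, 10, n_zero_terminals=7, element_id="below")
        retained, log = filter_trees([at, below], fg)
        assert [t.element_id for t in retained] == ["below"]
        assert log[0].rule == "zero_fraction"

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_trees([], {"A", "B"})


class TestAverageTree:
    def test_identical_trees_recovered(self, master4):
        trees = [
            make_element(master4, "ABCD", {k: v for k, v in
                         [("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 4.0),
                          ("AB", 0.5), ("CD", 1.5)]})
            for _ in range(3)
        ]
        for i, t in enumerate(trees):
            t.element_id = f"e{i}"
        avg = estimate_average_tree(RateMatrix.from_trees(trees, master4))
        assert avg.avg_lengths["A"] == pytest.approx(1.0)
        assert avg.avg_lengths["anc02"] == pytest.approx(1.5)

    def test_scalar_multiples_average_proportional(self, master4):
        base = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "AB": 0.5, "CD": 1.5}
        trees = []
        for i, c in enumerate([1.0, 2.0, 3.0]):
            t = make_element(master4, "ABCD", {k: c * v for k, v in base.items()})
            t.element_id = f"e{i}"
            trees.append(t)
        avg = estimate_average_tree(RateMatrix.from_trees(trees, master4))
        got = np.array([avg.avg_lengths[b] for b in ["A", "B", "C", "D"]])
        ratio = got / np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_merged_paths_excluded_from_singleton_means(self, master4):
        full = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "AB": 0.5, "CD": 1.5}
        t1 = make_element(master4, "ABCD", full)
        t1.element_id = "full1"
        t2 = make_element(master4, "ABCD", {k: 2 * v for k, v in full.items()})
        t2.element_id = "full2"
        # drops D; its C branch is a merged C+CD path and must not feed
        # the singleton means of either C or CD
        t3 = make_element(master4, "ABC", {"A": 99.0, "B": 99.0, "AB": 99.0, "C": 99.0})
        t3.element_id = "noD"
        matrix = RateMatrix.from_trees([t1, t2, t3], master4)
        singleton = matrix.singleton_mask()
        row = list(matrix.values.index).index("noD")
        col_c = list(matrix.values.columns).index("C")
        assert not singleton[row, col_c]
        assert np.isnan(matrix.values.loc["noD", "anc02"])

    def test_unobserved_branch_errors(self, master4):
        t1 = make_element(master4, "ABC", {})
        t1.element_id = "x1"
        t2 = make_element(master4, "ABC", {})
        t2.element_id = "x2"
        with pytest.raises(ValueError, match="never observed"):
            estimate_average_tree(RateMatrix.from_trees([t1, t2], master4))


def matrix_from_rows(master, rows):
    """RateMatrix from a dict of element -> {branch_id: value} (no merging)."""
    frame = pd.DataFrame(rows).T.reindex(columns=list(master.branch_ids))
    return RateMatrix(frame, merged={}, master=master)


class TestComputeRER:
    def test_proportional_vector_gives_zero(self, master4):
        avg = master4.with_avg_lengths(
            {"A": 1, "B": 2, "C": 3, "D": 6, "anc01": 4, "anc02": 5}
        )
        mat = matrix_from_rows(
            master4, {"e": {"A": 2, "B": 4, "C": 6, "D": 12, "anc01": 8, "anc02": 10}}
        )
        rer = compute_rer(mat, avg)
        assert rer.beta["e"] == pytest.approx(2.0)
        assert np.allclose(rer.values.loc["e"].to_numpy(), 0.0, atol=1e-12)

    def test_two_branch_arithmetic(self, master2):
        avg = master2.with_avg_lengths({"A": 1.0, "B": 2.0})
        mat = matrix_from_rows(master2, {"e": {"A": 3.0, "B": 2.0}})
        rer = compute_rer(mat, avg)
        assert rer.beta["e"] == pytest.approx(1.4)
        assert rer.values.loc["e", "A"] == pytest.approx(1.6)
        assert rer.values.loc["e", "B"] == pytest.approx(-0.8)
        # residual orthogonal to the expectation
        assert rer.values.loc["e"] @ np.array([1.0, 2.0]) == pytest.approx(0.0, abs=1e-12)

    def test_single_present_branch_residual_zero(self, master4):
        avg = master4.with_avg_lengths({b: 1.0 for b in master4.branch_ids})
        mat = matrix_from_rows(master4, {"e": {"A": 7.3}})
        rer = compute_rer(mat, avg)
        assert rer.values.loc["e", "A"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_expectations_error(self, master2):
        avg = master2.with_avg_lengths({"A": 0.0, "B": 0.0})
        mat = matrix_from_rows(master2, {"e": {"A": 1.0, "B": 2.0}})
        with pytest.raises(ValueError, match="degenerate"):
            compute_rer(mat, avg)

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(min_value=0.05, max_value=20.0))
    def test_scale_equivariance(self, c):
        master = simulate_master_tree(8, seed=11)
        sim = simulate_element_trees(
            SimulationConfig(n_taxa=8, n_elements=6, min_species=8, dropout=0.0,
                             zero_prob=0.0, seed=11),
            master=master,
        )
        matrix = RateMatrix.from_trees(sim.trees, master)
        scaled_trees = [
            ElementTree(t.element_id, t.taxa, {k: c * v for k, v in t.lengths.items()})
            for t in sim.trees
        ]
        matrix_c = RateMatrix.from_trees(scaled_trees, master)
        r1 = compute_rer(matrix, master)
        r2 = compute_rer(matrix_c, master)
        assert np.allclose(
            r2.values.to_numpy(), c * r1.values.to_numpy(), rtol=1e-9, atol=1e-12
        )
        s1 = compute_rer(matrix, master, scale="element")
        s2 = compute_rer(matrix_c, master, scale="element")
        assert np.allclose(s2.values.to_numpy(), s1.values.to_numpy(), rtol=1e-9, atol=1e-9)


class TestPipelineProperties:
    def test_orthogonality_on_simulated_run(self, small_sim):
        retained, _ = filter_trees(small_sim.trees, small_sim.foreground)
        matrix = RateMatrix.from_trees(retained, small_sim.master)
        avg = estimate_average_tree(matrix)
        rer = compute_rer(matrix, avg)
        E = matrix.expected_matrix(
            np.array([avg.avg_lengths[b] for b in matrix.values.columns])
        )
        dots = np.nansum(np.where(np.isnan(E), 0.0, rer.values.to_numpy() * E), axis=1)
        assert np.max(np.abs(dots)) < 1e-8

    def test_average_tree_fixed_point(self):
        # data generated exactly as s_g * A (no noise, no dropout)
        master = simulate_master_tree(10, seed=5)
        sim = simulate_element_trees(
            SimulationConfig(n_taxa=10, n_elements=20, min_species=10, dropout=0.0,
                             zero_prob=0.0, noise_sdlog=0.0, fg_multiplier=1.0,
                             planted_fraction=0.0, seed=5),
            master=master,
        )
        matrix = RateMatrix.from_trees(sim.trees, master)
        est = estimate_average_tree(matrix)
        truth = np.array([master.avg_lengths[b] for b in master.branch_ids])
        got = np.array([est.avg_lengths[b] for b in master.branch_ids])
        ratio = got / truth
        assert np.max(np.abs(ratio / ratio[0] - 1.0)) < 1e-6

    def test_null_foreground_background_distributions_match(self):
        # equal master branch lengths isolate fg/bg exchangeability from the
        # residual-spread dependence on branch length
        from scipy.stats import ks_2samp

        base = simulate_master_tree(39, seed=0)
        master = base.with_avg_lengths({b: 0.05 for b in base.branch_ids})
        sim = simulate_element_trees(
            SimulationConfig(fg_multiplier=1.0, seed=0), master=master
        )
        retained, _ = filter_trees(sim.trees, sim.foreground)
        matrix = RateMatrix.from_trees(retained, master)
        rer = compute_rer(matrix, estimate_average_tree(matrix))
        tf = rer.terminal_frame()
        fg = list(sim.foreground)
        bg = [c for c in tf.columns if c not in fg]
        a = tf[fg].to_numpy().ravel()
        b = tf[bg].to_numpy().ravel()
        p = ks_2samp(a[~np.isnan(a)], b[~np.isnan(b)]).pvalue
        assert p > 0.01
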