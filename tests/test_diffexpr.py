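"""DE caller, BH adjustment, ncRNA expression calling, and Ward clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gravsig.diffexpr import (
    ExpressionMatrix,
    bh_adjust,
    call_degs,
    call_expressed_ncrna,
    cluster_samples,
    test_differential_expression as de_stats,
)
from gravsig.simulate import ExpressionSimConfig, generate_expression


def make_matrix(rows: dict[str, list[float]], conditions: dict[str, list[str]]):
    """rows: gene -> values; conditions: condition -> sample ids."""
    design = {}
    columns = []
    for cond, samples in conditions.items():
        for i, s in enumerate(samples, start=1):
            design[s] = (cond, i)
            columns.append(s)
    values = pd.DataFrame(rows, index=columns).T
    return ExpressionMatrix(values=values, design=design)


TWO_COND = {"T": ["t1", "t2", "t3"], "C": ["c1", "c2", "c3"]}


class TestDifferentialExpression:
    def test_exact_fourfold_ratio_gives_log2fc_two(self):
        m = make_matrix({"g1": [16, 16, 16, 4, 4, 4]}, TWO_COND)
        res = de_stats(m, "T", "C", pseudocount=1e-9)
        assert res.loc[0, "log2fc"] == pytest.approx(2.0, abs=1e-6)

    def test_identical_groups_give_zero_fc_unit_p(self):
        m = make_matrix({"g1": [5, 6, 7, 5, 6, 7]}, TWO_COND)
        res = de_stats(m, "T", "C")
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_p_value_matches_hand_computed_pooled_t(self):
        # (2,3,4) vs (6,7,8) on the raw scale: log transform undone by
        # using 2**x - 1 as input so the log2(x+1) values are exactly 2,3,4/6,7,8
        vals = [2**v - 1 for v in (6, 7, 8, 2, 3, 4)]
        m = make_matrix({"g1": vals}, TWO_COND)
        res = de_stats(m, "T", "C")
        # pooled t: means 7 vs 3, s_p^2 = 1, t = 4/sqrt(2/3), df = 4
        assert res.loc[0, "log2fc"] == pytest.approx(4.0)
        assert res.loc[0, "p_raw"] == pytest.approx(0.008049893100837719, rel=1e-9)

    def test_zero_variance_unequal_means_warns_p_zero(self):
        m = make_matrix({"g1": [8, 8, 8, 2, 2, 2]}, TWO_COND)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            res = de_stats(m, "T", "C")
        assert res.loc[0, "p_raw"] == 0.0

    def test_single_replicate_condition_rejected_by_name(self):
        m = make_matrix(
            {"g1": [1, 2, 3, 4]}, {"T": ["t1", "t2", "t3"], "C": ["c1"]}
        )
        with pytest.raises(ValueError, match="'C'"):
            de_stats(m, "T", "C")

    def test_direction_conservation_under_contrast_flip(self):
        m, _ = generate_expression(
            ExpressionSimConfig(n_genes=100, conditions=("GC", "MG"), seed=5)
        )
        fwd = de_stats(m, "MG", "GC")
        rev = de_stats(m, "GC", "MG")
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)
        t_f = call_degs(fwd, treatment="MG", control="GC")
        t_r = call_degs(rev, treatment="GC", control="MG")
        assert t_f.up_ids == t_r.down_ids and t_f.down_ids == t_r.up_ids


def bh_oracle(p):
    """Sort, scale by m/rank, running minimum from the largest rank, unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_output_at_least_input_pointwise(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        assert np.all(bh_adjust(p) >= p)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestCallDegs:
    def make_stats(self, log2fc, p_raw):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(log2fc))],
             "log2fc": log2fc, "p_raw": p_raw}
        )

    def test_threshold_logic_with_strict_inequalities(self):
        stats = self.make_stats([2.5, 2.0, -2.5, 0.1], [0.001, 0.001, 0.001, 0.001])
        table = call_degs(stats)
        calls = dict(zip(table.records["gene_id"], table.records["call"]))
        assert calls["g0"] == "up"
        assert calls["g1"] == "not_de"  # boundary: strict >
        assert calls["g2"] == "down"
        assert calls["g3"] == "not_de"

    def test_relaxed_threshold_admits_weaker_folds(self):
        stats = self.make_stats([1.8, -1.7], [0.001, 0.001])
        strict = call_degs(stats, fc_threshold=2.0)
        relaxed = call_degs(stats, fc_threshold=1.5)
        assert strict.de_ids == set()
        assert relaxed.up_ids == {"g0"} and relaxed.down_ids == {"g1"}

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            call_degs(self.make_stats([], []))

    def test_null_data_false_positive_rate_below_alpha(self):
        # frac_de=0: the caller's DEG rate stays within alpha + MC noise
        fp = 0
        genes = 0
        for seed in range(5):
            m, _ = generate_expression(
                ExpressionSimConfig(
                    n_genes=1000, conditions=("GC", "MG"), frac_de=0.0, seed=seed
                )
            )
            table = call_degs(
                de_stats(m, "MG", "GC"),
                treatment="MG", control="GC",
            )
            fp += len(table.de_ids)
            genes += 1000
        assert fp / genes <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / genes)


class TestCallExpressedNcrna:
    def matrix(self):
        return make_matrix(
            {
                "nc1": [30, 30, 30, 20, 20, 20],
                "nc2": [24.7, 24.7, 24.7, 10, 10, 10],
                "nc3": [1, 1, 1, 100, 100, 100],
                "g1": [5, 5, 5, 5, 5, 5],
            },
            {"MG": ["m1", "m2", "m3"], "GC": ["c1", "c2", "c3"]},
        )

    def test_cutoff_applied_inclusively_per_condition_mean(self):
        sets = call_expressed_ncrna(self.matrix(), ["nc1", "nc2", "nc3"])
        assert sets["MG"] == {"nc1", "nc2"}  # 24.7 counts as expressed
        assert sets["GC"] == {"nc3"}

    def test_zero_cutoff_makes_everything_expressed(self):
        sets = call_expressed_ncrna(self.matrix(), ["nc1", "nc2", "nc3"], cutoff=0.0)
        assert sets["MG"] == sets["GC"] == {"nc1", "nc2", "nc3"}

    def test_unknown_ids_reported(self):
        with pytest.raises(KeyError, match="ghost"):
            call_expressed_ncrna(self.matrix(), ["nc1", "ghost"])


class TestClusterSamples:
    def test_identical_samples_merge_at_height_zero(self):
        m = make_matrix(
            {"g1": [4, 4, 50], "g2": [7, 7, 60]},
            {"A": ["a1", "a2"], "B": ["b1"]},
        )
        d = cluster_samples(m)
        first_a, first_b = d.merge_order()[0]
        assert first_a | first_b == {"a1", "a2"}
        assert d.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_near_pair_merges_before_distant_sample(self):
        m = make_matrix(
            {"g1": [1.0, 1.1, 9.0], "g2": [2.0, 2.1, 30.0]},
            {"A": ["a1", "a2"], "B": ["b1"]},
        )
        sa, sb = cluster_samples(m).merge_order()[0]
        assert sa | sb == {"a1", "a2"}

    def test_four_point_merge_order_matches_hand_run_ward(self):
        # two tight pairs far apart: Ward merges each pair first, then joins
        m = make_matrix(
            {"g1": [0, 0, 31, 31], "g2": [0, 0.5, 31, 31.5]},
            {"A": ["a1", "a2"], "B": ["b1", "b2"]},
        )
        order = cluster_samples(m, log_transform=False).merge_order()
        first_two = {frozenset(a | b) for a, b in order[:2]}
        assert first_two == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
        assert order[2][0] | order[2][1] == {"a1", "a2", "b1", "b2"}

    def test_constant_matrix_yields_degenerate_tree(self):
        m = make_matrix(
            {"g1": [3, 3, 3], "g2": [3, 3, 3]},
            {"A": ["a1", "a2"], "B": ["b1"]},
        )
        d = cluster_samples(m)
        assert np.allclose(d.linkage[:, 2], 0.0)
        assert d.to_newick().endswith(";")

    def test_newick_is_parseable_and_covers_all_samples(self):
        from io import StringIO

        from Bio import Phylo

        m, _ = generate_expression(
            ExpressionSimConfig(n_genes=50, conditions=("GC", "MG"), seed=1)
        )
        nwk = cluster_samples(m).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == set(m.sample_ids)


class TestExpressionMatrixInvariants:
    def test_duplicate_gene_ids_rejected(self):
        values = pd.DataFrame(
            [[1, 2], [3, 4]], index=["g1", "g1"], columns=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="duplicate gene ids"):
            ExpressionMatrix(values=values, design={"s1": ("A", 1), "s2": ("A", 2)})

    def test_negative_values_rejected(self):
        values = pd.DataFrame([[1, -2]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(values=values, design={"s1": ("A", 1), "s2": ("A", 2)})
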