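"""Generator contracts: determinism, exact integer structure, noise behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gravsig import calibration as cal
from gravsig.simulate import (
    ExpressionSimConfig,
    LipidSimConfig,
    OverlapSimConfig,
    generate_expression,
    generate_lipid_panel,
    generate_overlap_lists,
)


def small_expr_config(**kw) -> ExpressionSimConfig:
    base = dict(
        n_genes=300,
        conditions=("GC", "MG", "R1"),
        n_replicates=3,
        frac_de=0.1,
        persistence={"R1": 0.75},
        seed=7,
    )
    base.update(kw)
    return ExpressionSimConfig(**base)


class TestGenerateExpression:
    def test_deterministic_given_seed(self):
        cfg = small_expr_config()
        m1, t1 = generate_expression(cfg)
        m2, t2 = generate_expression(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.effects == t2.effects

    def test_different_seed_differs(self):
        m1, _ = generate_expression(small_expr_config(seed=1))
        m2, _ = generate_expression(small_expr_config(seed=2))
        assert not m1.values.equals(m2.values)

    def test_null_config_has_no_de_genes(self):
        _, truth = generate_expression(small_expr_config(frac_de=0.0))
        assert all(len(eff) == 0 for eff in truth.effects.values())

    def test_values_finite_nonnegative(self):
        m, _ = generate_expression(small_expr_config())
        arr = m.values.to_numpy()
        assert np.all(np.isfinite(arr)) and np.all(arr >= 0)

    def test_persistence_fraction_exact_by_construction(self):
        cfg = ExpressionSimConfig(
            n_genes=5000, conditions=("GC", "MG", "R1"), frac_de=0.1,
            persistence={"R1": 0.75}, seed=3,
        )
        _, truth = generate_expression(cfg)
        mg = truth.de_ids("MG")
        r1 = truth.de_ids("R1")
        assert len(mg) == 500
        assert len(r1 & mg) / len(mg) == 0.75
        # retained genes keep the exposure direction
        for g in r1:
            assert truth.effects["R1"][g] == truth.effects["MG"][g]

    def test_direction_split_follows_frac_up(self):
        _, truth = generate_expression(small_expr_config(frac_up=0.6))
        up = truth.de_ids("MG", "up")
        down = truth.de_ids("MG", "down")
        assert len(up) == round(0.6 * 30)
        assert len(up) + len(down) == 30

    def test_subset_persistence_overrides_global(self):
        cfg = cal.tf_expression_config(5)
        _, truth = generate_expression(cfg)
        tf = set(cfg.tf_gene_ids)
        assert tf <= truth.de_ids("MG", "up")
        for tp, frac in (("R1_GC", 0.90), ("R2_GC", 0.75), ("R3_GC", 0.15)):
            kept = truth.de_ids(tp, "up") & tf
            assert len(kept) == round(frac * 20)

    def test_shipped_persistence_fractions_non_increasing(self):
        cfg = cal.expression_config(0)
        for d in ("up", "down"):
            fracs = [
                p[d] if isinstance(p, dict) else p
                for p in (cfg.persistence[t] for t in ("R1_GC", "R2_GC", "R3_GC"))
            ]
            assert fracs == sorted(fracs, reverse=True)

    def test_fpkm_mode_scales_by_library_size(self):
        cfg = small_expr_config(output="fpkm")
        m, _ = generate_expression(cfg)
        counts, _ = generate_expression(small_expr_config(output="counts"))
        col = m.values.columns[0]
        lib = counts.values[col].sum()
        expected = counts.values[col] / (lib / 1e6)
        np.testing.assert_allclose(m.values[col], expected)

    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_de": 1.5},
            {"frac_up": -0.1},
            {"n_replicates": 1},
            {"nb_dispersion": 0.0},
            {"persistence": {"R1": 1.2}},
            {"persistence": {"NOPE": 0.5}},
            {"tf_gene_ids": ("not_a_gene",)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            generate_expression(small_expr_config(**kw))


class TestGenerateLipidPanel:
    def test_deterministic(self):
        cfg = cal.lipid_config(3)
        p1, _ = generate_lipid_panel(cfg)
        p2, _ = generate_lipid_panel(cfg)
        pd.testing.assert_frame_equal(p1.concentrations, p2.concentrations)

    def test_noise_free_limit_recovers_fold_exactly(self):
        cfg = LipidSimConfig(
            species=("a", "b", "c"),
            control_mean={"a": 10.0, "b": 5.0, "c": 50.0},
            fold_change={"a": 2.0, "b": 0.5, "c": 1.0},
            cv=0.0,
            seed=0,
        )
        panel, _ = generate_lipid_panel(cfg)
        ctrl = panel.kept_values("control").mean(axis=1)
        trt = panel.kept_values("treatment").mean(axis=1)
        np.testing.assert_allclose(trt["a"] / ctrl["a"], 2.0)
        np.testing.assert_allclose(trt["b"] / ctrl["b"], 0.5)

    def test_concentrations_strictly_positive(self):
        panel, _ = generate_lipid_panel(cal.lipid_config(11))
        assert (panel.concentrations.to_numpy() > 0).all()

    def test_outlier_profile_has_target_correlation(self):
        cfg = cal.lipid_config(9)
        panel, truth = generate_lipid_panel(cfg)
        assert truth.outlier_replicate == "control_r3"
        log = np.log(panel.concentrations)
        honest = log["control_r1"]
        outlier = log[truth.outlier_replicate]
        r2 = np.corrcoef(honest, outlier)[0, 1] ** 2
        assert r2 < 0.8  # far below the QC threshold, near the 0.6 target

    def test_null_folds_reject_at_nominal_rate(self):
        # fold=1 for every species: the two-tailed test should reject ~5%
        species = tuple("s%d" % i for i in range(4))
        rejections = 0
        trials = 0
        from scipy import stats as sps

        for seed in range(300):
            cfg = LipidSimConfig(
                species=species,
                control_mean={s: 50.0 for s in species},
                fold_change={s: 1.0 for s in species},
                cv=0.2,
                seed=seed,
            )
            panel, _ = generate_lipid_panel(cfg)
            ctrl = panel.kept_values("control")
            trt = panel.kept_values("treatment")
            for sp in species:
                _, p = sps.ttest_ind(trt.loc[sp], ctrl.loc[sp], equal_var=True)
                rejections += p < 0.05
                trials += 1
        rate = rejections / trials
        se = np.sqrt(0.05 * 0.95 / trials)
        assert rate < 0.05 + 4 * se
        assert rate > 0.05 - 4 * se

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            LipidSimConfig(
                species=("a",), control_mean={"a": 0.0}, fold_change={"a": 1.0}
            ).validate()


class TestGenerateOverlapLists:
    def test_counts_exact_set_algebra(self):
        cfg = OverlapSimConfig(
            universe_size=1000, n_degs_study_a=80, n_degs_study_b=50,
            n_shared=20, n_conflicting=4, seed=2,
        )
        a, b = generate_overlap_lists(cfg)
        assert len(a.de_ids) == 80 and len(b.de_ids) == 50
        shared = a.de_ids & b.de_ids
        assert len(shared) == 20
        da, db = a.directions(), b.directions()
        conflicts = {g for g in shared if da[g] != db[g]}
        assert len(conflicts) == 4

    def test_zero_shared_gives_disjoint_lists(self):
        cfg = OverlapSimConfig(
            universe_size=500, n_degs_study_a=30, n_degs_study_b=30,
            n_shared=0, n_conflicting=0, seed=1,
        )
        a, b = generate_overlap_lists(cfg)
        assert not (a.de_ids & b.de_ids)

    def test_deterministic(self):
        cfg = cal.overlap_config(4)
        a1, b1 = generate_overlap_lists(cfg)
        a2, b2 = generate_overlap_lists(cfg)
        pd.testing.assert_frame_equal(a1.records, a2.records)
        pd.testing.assert_frame_equal(b1.records, b2.records)

    @settings(max_examples=30, deadline=None)
    @given(
        n_a=st.integers(1, 40),
        n_b=st.integers(1, 40),
        data=st.data(),
    )
    def test_random_configs_match_set_oracle(self, n_a, n_b, data):
        n_shared = data.draw(st.integers(0, min(n_a, n_b)))
        n_conf = data.draw(st.integers(0, n_shared))
        seed = data.draw(st.integers(0, 2**16))
        cfg = OverlapSimConfig(
            universe_size=200, n_degs_study_a=n_a, n_degs_study_b=n_b,
            n_shared=n_shared, n_conflicting=n_conf, seed=seed,
        )
        a, b = generate_overlap_lists(cfg)
        shared = a.de_ids & b.de_ids
        assert len(shared) == n_shared
        da, db = a.directions(), b.directions()
        assert sum(da[g] != db[g] for g in shared) == n_conf

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_shared": 200},  # exceeds smaller list
            {"n_conflicting": 140},  # exceeds shared
            {"universe_size": 100},  # smaller than union
        ],
    )
    def test_infeasible_counts_rejected(self, kw):
        base = dict(
            universe_size=20000, n_degs_study_a=150, n_degs_study_b=120,
            n_shared=100, n_conflicting=10, seed=0,
        )
        base.update(kw)
        with pytest.raises(ValueError):
            OverlapSimConfig(**base).validate()
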