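"""Permutation ANCOVA, BH-FDR, permuted Tukey contrasts, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alphasync.group_stats import (Design, ancova_f, compare_scalar_ancova,
                                   correlate_scores, edge_stats_table, fdr_bh,
                                   permutation_ancova,
                                   tukey_pairwise_permuted)


def _design(n_per_group=8, age_effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["HC", "SCD", "MCI"], n_per_group)
    age = rng.uniform(65, 80, size=groups.size)
    ids = [f"S{i}" for i in range(groups.size)]
    return Design(ids, groups, age), rng


class TestAncovaF:
    def test_matches_statsmodels_type_two(self):
        """Closed-form regression oracle: Type-II group F from statsmodels
        OLS + anova_lm on a hand-set fixture."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        groups = np.repeat(["HC", "SCD", "MCI"], 4)
        age = np.array([70, 72, 75, 68, 71, 74, 69, 73, 76, 70, 72, 77.0])
        y = rng.normal(size=12) + (groups == "MCI") * 1.5 + 0.1 * age
        design = Design([f"S{i}" for i in range(12)], groups, age)
        f_ours = ancova_f(y, design)
        df = pd.DataFrame({"y": y, "group": groups, "age": age})
        fit = smf.ols("y ~ C(group) + age", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert f_ours == pytest.approx(tab.loc["C(group)", "F"], rel=1e-10)

    def test_degenerate_constant_values_give_zero(self):
        design, _ = _design()
        assert ancova_f(np.ones(design.n), design) == 0.0

    def test_row_permutation_invariance(self):
        """Permuting subjects jointly (values, group, age) leaves F fixed."""
        design, rng = _design(seed=5)
        y = rng.normal(size=design.n)
        f0 = ancova_f(y, design)
        perm = rng.permutation(design.n)
        d2 = Design([design.subject_ids[i] for i in perm],
                    design.groups[perm], design.age[perm])
        assert ancova_f(y[perm], d2) == pytest.approx(f0, rel=1e-10)

    def test_rank_deficient_design_rejected(self):
        groups = np.repeat(["HC", "SCD", "MCI"], 4)
        age = np.where(groups == "MCI", 80.0, np.where(groups == "SCD",
                                                       70.0, 60.0))
        design = Design([f"S{i}" for i in range(12)], groups, age)
        with pytest.raises(ValueError, match="rank"):
            ancova_f(np.arange(12.0), design)

    def test_too_few_subjects_rejected(self):
        design = Design(["a", "b", "c", "d"],
                        np.array(["HC", "HC", "MCI", "MCI"]),
                        np.array([70, 71, 74, 75.0]))
        with pytest.raises(ValueError, match="n >"):
            ancova_f(np.arange(4.0), design)


class TestPermutationAncova:
    def test_deterministic_given_seed(self):
        design, rng = _design(seed=1)
        v = rng.normal(size=(design.n, 5))
        a = permutation_ancova(v, design, n_perm=200, seed=11)
        b = permutation_ancova(v, design, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_massive_effect_hits_permutation_floor(self):
        design, rng = _design(seed=2)
        v = rng.normal(size=design.n) + 50.0 * (design.groups == "MCI")
        res = permutation_ancova(v, design, n_perm=200, seed=0)
        assert res["p_perm"].iloc[0] == pytest.approx(1.0 / 201.0)

    def test_null_type_one_rate_near_alpha(self):
        """Small null calibration: P(p ≤ 0.05) close to 0.05 over many
        independent null edges (the full-scale check lives in the
        acceptance suite)."""
        design, rng = _design(n_per_group=15, seed=3)
        v = rng.normal(size=(design.n, 300)) + 0.05 * design.age[:, None]
        res = permutation_ancova(v, design, n_perm=200, seed=4)
        rate = (res["p_perm"] <= 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_n_perm_minimum_enforced(self):
        design, rng = _design()
        with pytest.raises(ValueError):
            permutation_ancova(rng.normal(size=design.n), design, n_perm=10)


class TestFdrBH:
    def test_stepup_rule_fixture(self):
        mask, thr = fdr_bh(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, True, False]
        assert thr == pytest.approx(0.03)

    def test_all_ones_no_rejections(self):
        mask, _ = fdr_bh(np.ones(20), q=0.05)
        assert not mask.any()

    def test_empty_input(self):
        mask, thr = fdr_bh(np.array([]))
        assert mask.size == 0 and thr == 0.0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=30)
    def test_agrees_with_direct_stepup_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        mask, _ = fdr_bh(p, q=0.05)
        # direct enumeration of the step-up definition
        order = np.argsort(p)
        m = p.size
        k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * 0.05 / m:
                k = rank
        expected = np.zeros(m, bool)
        expected[order[:k]] = True
        assert mask.tolist() == expected.tolist()

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(size=500) ** 2
        mask, _ = fdr_bh(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert (mask == ref).all()


class TestTukeyPermuted:
    def test_shifted_group_two_contrasts_significant(self):
        design, rng = _design(n_per_group=12, seed=6)
        v = rng.normal(size=design.n) + 8.0 * (design.groups == "MCI")
        out = tukey_pairwise_permuted(v, design, n_perm=400, seed=1)
        out = out.set_index(["group_a", "group_b"])
        assert out.loc[("HC", "MCI"), "p_corrected"] < 0.01
        assert out.loc[("SCD", "MCI"), "p_corrected"] < 0.01
        assert out.loc[("HC", "SCD"), "p_corrected"] > 0.2

    def test_direction_sign_contract(self):
        design, rng = _design(n_per_group=12, seed=7)
        v = rng.normal(size=design.n) + 5.0 * (design.groups == "SCD")
        out = tukey_pairwise_permuted(v, design, n_perm=200, seed=2)
        out = out.set_index(["group_a", "group_b"])
        # difference is (first − second) of the pair, age-adjusted
        assert out.loc[("HC", "SCD"), "difference"] < 0
        assert out.loc[("SCD", "MCI"), "difference"] > 0

    def test_null_no_spurious_contrasts(self):
        design, rng = _design(n_per_group=12, seed=8)
        v = rng.normal(size=(design.n, 10))
        out = tukey_pairwise_permuted(v, design, n_perm=300, seed=3)
        assert (out["p_corrected"] < 0.01).sum() == 0


class TestCorrelateScores:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(9)
        edge = rng.normal(size=(30, 1))
        scores = pd.DataFrame({"MMSE": edge[:, 0]})
        out = correlate_scores(edge, ["e1"], scores)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["fdr_rejected"].iloc[0]

    def test_negative_sign_recovered(self):
        rng = np.random.default_rng(10)
        edge = rng.normal(size=(40, 1))
        scores = pd.DataFrame({"BNT": -edge[:, 0] + rng.normal(
            scale=0.2, size=40)})
        out = correlate_scores(edge, ["e1"], scores)
        assert out["r"].iloc[0] < -0.9

    def test_zero_variance_rejected(self):
        edge = np.ones((10, 1))
        scores = pd.DataFrame({"MMSE": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            correlate_scores(edge, ["e1"], scores)

    def test_joint_fdr_family(self):
        rng = np.random.default_rng(11)
        edges = rng.normal(size=(25, 4))
        scores = pd.DataFrame({"a": rng.normal(size=25),
                               "b": rng.normal(size=25)})
        out = correlate_scores(edges, list("wxyz"), scores)
        assert len(out) == 8  # 4 edges × 2 scores, one family


class TestScalarAncova:
    def test_lowered_mci_volume_detected(self):
        design, rng = _design(n_per_group=20, seed=12)
        vol = rng.normal(5.0e-3, 0.5e-3, size=design.n)
        vol[design.groups == "MCI"] -= 0.6e-3
        res = compare_scalar_ancova(vol, design, n_perm=500, seed=5)
        assert res["p_perm"] < 0.01
        pw = res["pairwise"].set_index(["group_a", "group_b"])
        assert pw.loc[("HC", "MCI"), "p_corrected"] < 0.05
        assert pw.loc[("SCD", "MCI"), "p_corrected"] < 0.05
        assert pw.loc[("HC", "SCD"), "p_corrected"] > 0.1

    def test_null_volumes_not_significant(self):
        design, rng = _design(n_per_group=20, seed=13)
        vol = rng.normal(5.0e-3, 0.5e-3, size=design.n)
        res = compare_scalar_ancova(vol, design, n_perm=300, seed=6)
        assert res["p_perm"] > 0.05

    def test_constant_input_degenerate_f_handled(self):
        design, _ = _design(n_per_group=10)
        res = compare_scalar_ancova(np.full(design.n, 4.4e-3), design,
                                    n_perm=200, seed=7)
        assert res["F"] == 0.0 and res["p_perm"] == 1.0


def test_edge_stats_table_end_to_end():
    design, rng = _design(n_per_group=15, seed=14)
    v = rng.normal(size=(design.n, 20))
    v[:, 3] += 4.0 * (design.groups == "MCI")
    names = [f"e{i}" for i in range(20)]
    table, pairwise = edge_stats_table(v, design, names, n_perm=400, seed=8)
    assert table.loc[table["edge"] == "e3", "fdr_rejected"].item()
    assert set(pairwise["edge"]) >= {"e3"}
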