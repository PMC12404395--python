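"""The six-stage statistical workflow, checked against brute-force
enumeration, closed-form 2x2 odds ratios, and rank-statistic identities."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aneumorph import (
    CohortSpec,
    WorkflowConfig,
    composite_scores,
    logistic_fit,
    make_cohort,
    mann_whitney,
    prune_collinear,
    roc_and_threshold,
    run_workflow,
    screen_parameters,
    validate_threshold,
)
from aneumorph.workflow import COMPOSITES, PARAMETERS, roc_curve_points


def two_group_frame(a, b, name="X", pair=("ruptured", "stable")):
    return pd.DataFrame({
        "id": [f"c{i}" for i in range(len(a) + len(b))],
        "group": [pair[0]] * len(a) + [pair[1]] * len(b),
        name: np.concatenate([a, b]),
    })


def exact_p_by_enumeration(a, b):
    """Two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mid = na * (n - na) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney(np.array([4.0, 5.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert u == 9.0  # every ruptured value beats every stable value
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = mann_whitney(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert p == 1.0

    def test_symmetry_in_arguments(self):
        a, b = np.array([1.0, 5.0, 9.0, 2.0]), np.array([3.0, 4.0, 8.0])
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])

    @pytest.mark.parametrize("seed", range(6))
    def test_against_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(3, 8), rng.integers(3, 8)
        a, b = rng.normal(size=na), rng.normal(1.0, size=nb) + 0.3
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(exact_p_by_enumeration(a, b), abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney(np.array([]), np.array([1.0]))


class TestScreening:
    def test_separated_parameter_retained(self):
        rng = np.random.default_rng(0)
        df = two_group_frame(rng.normal(10, 1, 20), rng.normal(0, 1, 20), "GLN")
        retained, means, pvals = screen_parameters(df)
        assert retained == ["GLN"]
        assert means.loc["GLN", "ruptured"] == pytest.approx(10, abs=1)
        assert pvals.loc["GLN", "ruptured_vs_stable"] < 1e-6

    def test_null_parameter_dropped(self):
        rng = np.random.default_rng(1)
        df = two_group_frame(rng.normal(size=30), rng.normal(size=30), "V")
        retained, _, pvals = screen_parameters(df)
        # same distribution: with alpha 0.05 this seed's p is well above it
        assert pvals.loc["V", "ruptured_vs_stable"] > 0.05
        assert retained == []

    def test_alpha_one_retains_everything_nonconstant(self):
        rng = np.random.default_rng(2)
        df = two_group_frame(rng.normal(size=10), rng.normal(size=10), "AR")
        retained, _, _ = screen_parameters(df, alpha=1.0)
        assert retained == ["AR"]

    def test_constant_parameter_warned_and_excluded(self):
        df = two_group_frame(np.full(5, 3.0), np.full(5, 3.0), "SR")
        with pytest.warns(UserWarning, match="zero variance"):
            retained, _, _ = screen_parameters(df, alpha=1.0)
        assert retained == []


class TestPruning:
    def make_df(self, cols, pvals_shift):
        """Columns with chosen pairwise structure; pvals_shift controls
        which member separates the groups better."""
        rng = np.random.default_rng(3)
        n = 40
        base = {"id": [f"c{i}" for i in range(2 * n)],
                "group": ["ruptured"] * n + ["stable"] * n}
        for name, arr in cols.items():
            base[name] = arr
        return pd.DataFrame(base)

    def test_duplicate_column_pruned_to_better_separator(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(2, 1, 40), rng.normal(0, 1, 40)])
        noise = rng.normal(scale=0.01, size=80)
        df = self.make_df({"WSS_max": x + noise, "WSS_rel_max": x}, 0)
        kept, corr = prune_collinear(df, ["WSS_rel_max", "WSS_max"])
        assert len(kept) == 1
        assert abs(corr.loc["WSS_max", "WSS_rel_max"]) > 0.99

    def test_moderate_correlation_untouched(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=80)
        df = self.make_df({"S": x, "V": y}, 0)
        kept, _ = prune_collinear(df, ["S", "V"])
        assert sorted(kept) == ["S", "V"]

    def test_result_independent_of_column_order(self):
        spec = CohortSpec(seed=99)
        cohort, _ = make_cohort(spec)
        retained, _, _ = screen_parameters(cohort, alpha=1.0)
        kept_fwd, _ = prune_collinear(cohort, retained)
        kept_rev, _ = prune_collinear(cohort, retained[::-1])
        assert sorted(kept_fwd) == sorted(kept_rev)

    def test_wss_pair_collapses_on_synthetic_cohort(self):
        cohort, _ = make_cohort(CohortSpec(seed=7))
        kept, corr = prune_collinear(cohort, ["WSS_rel_max", "WSS_max"])
        assert abs(corr.loc["WSS_rel_max", "WSS_max"]) > 0.95
        assert len(kept) == 1


class TestLogistic:
    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(8)
        df = two_group_frame(rng.normal(size=500), rng.normal(size=500), "GLN")
        fit = logistic_fit(df, ["GLN"])
        assert fit.loc["GLN", "estimable"]
        assert fit.loc["GLN", "OR"] == pytest.approx(1.0, abs=0.2)
        assert fit.loc["GLN", "CI_low"] < 1.0 < fit.loc["GLN", "CI_high"]
        assert fit.loc["GLN", "p"] > 0.05

    def test_binary_predictor_matches_2x2_cross_product(self):
        # ruptured: 30 exposed / 10 unexposed; stable: 12 / 28
        x = np.concatenate([np.ones(30), np.zeros(10), np.ones(12), np.zeros(28)])
        df = two_group_frame(x[:40], x[40:], "AR")
        fit = logistic_fit(df, ["AR"])
        expected = (30 * 28) / (10 * 12)
        assert fit.loc["AR", "OR"] == pytest.approx(expected, rel=1e-4)

    def test_unit_scaling_consistency(self):
        """Per-unit OR on x and on x/10 satisfy OR_scaled = OR**10."""
        rng = np.random.default_rng(9)
        a, b = rng.normal(1.2, 1, 200), rng.normal(0, 1, 200)
        df = two_group_frame(a, b, "S")
        df2 = df.copy()
        df2["S"] = df2["S"] / 10.0
        or1 = logistic_fit(df, ["S"]).loc["S", "OR"]
        or2 = logistic_fit(df2, ["S"]).loc["S", "OR"]
        assert or2 == pytest.approx(or1**10, rel=1e-3)

    def test_standardized_or_is_per_sd(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(1.0, 2, 300), rng.normal(0, 2, 300)
        df = two_group_frame(a, b, "V")
        sd = df["V"].std(ddof=0)
        raw = logistic_fit(df, ["V"]).loc["V", "OR"]
        std = logistic_fit(df, ["V"], standardize=True).loc["V", "OR"]
        assert std == pytest.approx(raw**sd, rel=1e-6)

    def test_perfect_separation_flagged_not_reported(self):
        df = two_group_frame(np.array([5.0, 6, 7, 8]), np.array([1.0, 2, 3, 4]),
                             "OSI_min")
        fit = logistic_fit(df, ["OSI_min"])
        assert not fit.loc["OSI_min", "estimable"]
        assert np.isnan(fit.loc["OSI_min", "OR"])

    def test_constant_predictor_rejected(self):
        df = two_group_frame(np.full(5, 1.0), np.full(5, 1.0), "SR")
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(df, ["SR"])


class TestComposites:
    def test_arithmetic(self):
        df = pd.DataFrame({"WSS_rel_max": [0.5, 2.0], "GLN": [2.0, 1.5],
                           "D_rel_max": [3.0, 0.4]})
        out = composite_scores(df)
        assert out["WG"].tolist() == pytest.approx([1.0, 3.0])
        assert out["GD"].tolist() == pytest.approx([6.0, 0.6])
        assert out["WGD"].tolist() == pytest.approx([3.0, 1.2])

    def test_wgd_is_wg_times_drel(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({c: rng.lognormal(size=50)
                           for c in ["WSS_rel_max", "GLN", "D_rel_max"]})
        out = composite_scores(df)
        assert np.allclose(out["WGD"], out["WG"] * df["D_rel_max"])

    def test_missing_factor_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            composite_scores(pd.DataFrame({"GLN": [1.0]}))

    def test_nan_record_skipped_with_warning(self):
        df = pd.DataFrame({"WSS_rel_max": [1.0, np.nan], "GLN": [1.0, 2.0],
                           "D_rel_max": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="skipped"):
            out = composite_scores(df)
        assert np.isnan(out.loc[1]).all()
        assert out.loc[0].notna().all()


class TestROC:
    def test_perfect_separation(self):
        res = roc_and_threshold(np.array([2.0, 3.0, 0.5, 0.9]),
                                np.array([1, 1, 0, 0]))
        assert res["AUC"] == 1.0
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0
        assert 0.9 <= res["threshold"] < 2.0

    def test_documented_tiny_example(self):
        """Ruptured {2.1, 1.5} vs stable {1.0, 1.8}: threshold 1.0 is the
        only one with sensitivity 1.0; its specificity is 0.5."""
        scores = np.array([2.1, 1.5, 1.0, 1.8])
        labels = np.array([1, 1, 0, 0])
        res = roc_and_threshold(scores, labels, sensitivity_target=0.8)
        assert res["threshold"] == pytest.approx(1.0)
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 0.5
        assert res["AUC"] == pytest.approx(0.75)

    def test_auc_equals_u_over_n1n2(self):
        rng = np.random.default_rng(12)
        pos, neg = rng.normal(1, 1, 37), rng.normal(0, 1, 53)
        u, _ = mann_whitney(pos, neg)
        res = roc_and_threshold(np.concatenate([pos, neg]),
                                np.r_[np.ones(37), np.zeros(53)])
        assert res["AUC"] == pytest.approx(u / (37 * 53), abs=1e-12)

    def test_negated_scores_complement_auc(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        a1 = roc_and_threshold(s, y)["AUC"]
        a2 = roc_and_threshold(-s, y)["AUC"]
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(14)
        for _ in range(10):
            s = rng.normal(size=80) + rng.integers(0, 2, 80)
            y = rng.integers(0, 2, 80)
            y[:2] = [0, 1]
            ours = roc_and_threshold(s, y)["AUC"]
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_curve_endpoints(self):
        thr, tpr, fpr = roc_curve_points(np.array([1.0, 2.0, 3.0]),
                                         np.array([0, 1, 1]))
        assert (tpr[0], fpr[0]) == (0.0, 0.0)
        assert (tpr[-1], fpr[-1]) == (1.0, 1.0)
        assert np.isinf(thr[0]) and np.isinf(thr[-1])

    def test_unreachable_target_warns_and_falls_back(self):
        scores = np.array([1.0, 1.0, 1.0, 2.0])
        labels = np.array([1, 1, 1, 0])
        with pytest.warns(UserWarning, match="sensitivity target"):
            res = roc_and_threshold(scores, labels, sensitivity_target=0.99)
        assert not res["target_met"]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve_points(np.array([1.0, 2.0]), np.array([1, 1]))


class TestValidation:
    def test_23_of_25(self):
        scores = np.r_[np.full(23, 2.0), np.full(2, 0.5)]
        k, n, pct = validate_threshold(scores, 1.1)
        assert (k, n) == (23, 25)
        assert pct == pytest.approx(92.0)

    def test_all_and_none(self):
        assert validate_threshold(np.full(10, 5.0), 1.0)[2] == 100.0
        assert validate_threshold(np.full(10, 0.5), 1.0)[2] == 0.0

    def test_threshold_itself_not_counted(self):
        k, _, _ = validate_threshold(np.array([1.1, 1.2]), 1.1)
        assert k == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            validate_threshold(np.array([]), 1.0)


class TestRunWorkflow:
    def test_end_to_end_determinism(self):
        cohort, val = make_cohort(CohortSpec(seed=21))
        r1 = run_workflow(cohort, val, WorkflowConfig(seed=21))
        r2 = run_workflow(cohort.copy(), val.copy(), WorkflowConfig(seed=21))
        assert r1.to_json() == r2.to_json()
        assert r1.config_hash == r2.config_hash

    def test_report_structure(self):
        cohort, val = make_cohort(CohortSpec(seed=22))
        rep = run_workflow(cohort, val)
        assert rep.group_sizes == {"ruptured": 58, "unruptured": 52, "stable": 15}
        assert set(rep.group_means.columns) == {"ruptured", "unruptured", "stable"}
        assert set(rep.pvalues.index) == set(PARAMETERS)
        # composites always reach the ROC stage
        assert set(COMPOSITES) <= set(rep.roc.index)
        assert set(rep.validation.index) == set(rep.roc.index)
        assert (rep.validation["n"] == 25).all()
        md = rep.to_markdown()
        for stage in ["Stage 1", "Stage 2", "Stage 3", "Stage 4", "Stage 5",
                      "Stage 6"]:
            assert stage in md

    def test_flipped_direction_recorded(self):
        # a parameter lower in ruptured cases must be auto-oriented
        cohort, val = make_cohort(CohortSpec(seed=23))
        rep = run_workflow(cohort, val)
        for name in rep.roc.index:
            assert rep.roc.loc[name, "AUC"] >= 0.5
            assert rep.roc.loc[name, "direction"] in (-1, 1)

    def test_missing_group_column_rejected(self):
        with pytest.raises(ValueError, match="group"):
            run_workflow(pd.DataFrame({"GLN": [1.0]}))

    def test_unknown_group_label_rejected(self):
        df = pd.DataFrame({"group": ["ruptured", "exploded"], "GLN": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unknown group"):
            run_workflow(df)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"id": ["a", "a"], "group": ["ruptured", "stable"],
                           "GLN": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            run_workflow(df)

    def test_stage_failures_are_attributed(self):
        df = pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "group": ["ruptured", "ruptured", "stable", "stable"],
            "GLN": [5.0, 6.0, 1.0, 2.0],
        })
        with pytest.raises(RuntimeError, match="workflow stage 'composites'"):
            run_workflow(df)
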