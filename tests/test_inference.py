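"""Cluster-level stratified estimation, covariate model, residuals, paired tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stratcrt.errors import (
    DegenerateWeightError,
    RankDeficiencyError,
    SeparationError,
    SmallStratumError,
)
from stratcrt.inference import (
    build_design_matrix,
    continuity_adjusted_p,
    fit_covariate_model,
    log_cluster_risks,
    paired_change_test,
    residualize,
    stratified_risk_difference,
    stratified_risk_ratio,
)


def summaries_from_props(props_by_arm, stratum="s1", period="endline", n=1000):
    """Build a summary frame with exact proportions (n chosen to keep o integral)."""
    rows = []
    i = 0
    for arm, props in props_by_arm.items():
        for p in props:
            rows.append({"cluster_id": f"c{i}", "stratum": stratum, "arm": arm,
                         "period": period, "o": round(p * n), "n": n})
            i += 1
    return pd.DataFrame(rows)


class TestLogClusterRisks:
    def test_plain_log(self):
        df = summaries_from_props({"control": [0.5, 0.5], "intervention": [0.5, 0.5]})
        out, meta = log_cluster_risks(df)
        assert np.allclose(out["log_risk"], math.log(0.5))
        assert meta["continuity_substitutions"] == 0

    def test_zero_event_continuity_substitution(self):
        df = pd.DataFrame({"cluster_id": ["c"], "stratum": ["s"], "arm": ["control"],
                           "period": ["endline"], "o": [0], "n": [9]})
        out, meta = log_cluster_risks(df)
        assert out["log_risk"].iloc[0] == pytest.approx(math.log(0.05))
        assert meta["continuity_substitutions"] == 1

    def test_zero_denominator_cluster_dropped(self):
        df = pd.DataFrame({"cluster_id": ["a", "b"], "stratum": ["s"] * 2,
                           "arm": ["control"] * 2, "period": ["endline"] * 2,
                           "o": [1, 0], "n": [4, 0]})
        out, meta = log_cluster_risks(df)
        assert len(out) == 1 and meta["dropped_zero_n"] == 1

    def test_full_event_boundary_also_substituted(self):
        assert continuity_adjusted_p(10, 10) == pytest.approx(10.5 / 11)


class TestStratifiedRiskRatio:
    def test_geometric_mean_oracle(self, oracle_summaries):
        est, strata = stratified_risk_ratio(oracle_summaries)
        assert est.point == pytest.approx(2.0, rel=1e-12)
        assert est.scale == "ratio"
        assert strata[0].c1 == strata[0].c0 == 2
        assert est.df == 2

    def test_identical_arms_give_unity(self):
        df = summaries_from_props({"control": [0.5, 0.4], "intervention": [0.5, 0.4]})
        est, _ = stratified_risk_ratio(df)
        assert est.point == pytest.approx(1.0)
        assert est.ci_low < 1 < est.ci_high

    def test_equal_stratum_ratios_pool_to_same_ratio(self):
        df = pd.concat([
            summaries_from_props({"control": [0.3, 0.2], "intervention": [0.6, 0.4]},
                                 stratum="s1"),
            summaries_from_props({"control": [0.1, 0.05], "intervention": [0.2, 0.1]},
                                 stratum="s2"),
        ], ignore_index=True)
        est, strata = stratified_risk_ratio(df)
        assert est.point == pytest.approx(2.0, rel=1e-12)
        assert sum(s.weight for s in strata) == pytest.approx(1.0)

    def test_arm_swap_inverts_ratio_and_keeps_p(self, oracle_summaries):
        est, _ = stratified_risk_ratio(oracle_summaries)
        swapped = oracle_summaries.assign(
            arm=oracle_summaries["arm"].map(
                {"control": "intervention", "intervention": "control"})
        )
        est_sw, _ = stratified_risk_ratio(swapped)
        assert est.point * est_sw.point == pytest.approx(1.0, rel=1e-12)
        assert est.p_value == pytest.approx(est_sw.p_value, rel=1e-12)

    def test_single_stratum_matches_unstratified_t(self, oracle_summaries):
        """With one stratum the machinery reduces to a two-sample t on log risks."""
        est, _ = stratified_risk_ratio(oracle_summaries)
        logs = np.log(oracle_summaries["o"] / oracle_summaries["n"])
        y1, y0 = logs[:2], logs[2:]
        t, p = stats.ttest_ind(y1, y0)
        assert est.t_stat == pytest.approx(t)
        assert est.p_value == pytest.approx(p)

    def test_spreadsheet_recomputation_small_instance(self):
        """Independent cellwise recomputation on a 6-cluster, 2-stratum instance."""
        df = pd.DataFrame({
            "cluster_id": list("abcdef"),
            "stratum": ["s1"] * 4 + ["s2"] * 2,
            "arm": ["intervention", "intervention", "control", "control"] * 1
                   + ["intervention", "control"],
            "period": ["endline"] * 6,
            "o": [12, 9, 6, 5, 8, 4],
            "n": [20, 20, 20, 20, 20, 20],
        })
        # stratum s2 has 1 cluster per arm -> hard error by default
        with pytest.raises(SmallStratumError):
            stratified_risk_ratio(df)
        df = df[df["stratum"] == "s1"]
        est, _ = stratified_risk_ratio(df)
        l = np.log(np.array([12, 9, 6, 5]) / 20)
        eff = l[:2].mean() - l[2:].mean()
        s2 = (np.var(l[:2], ddof=1) + np.var(l[2:], ddof=1)) / 2
        se = math.sqrt(s2 * (1 / 2 + 1 / 2))
        assert math.log(est.point) == pytest.approx(eff, rel=1e-12)
        assert est.se == pytest.approx(se, rel=1e-12)
        assert est.t_stat == pytest.approx(eff / se, rel=1e-12)
        assert est.df == 2

    def test_zero_variance_everywhere_is_degenerate(self):
        df = summaries_from_props({"control": [0.2, 0.2], "intervention": [0.4, 0.4]})
        with pytest.raises(DegenerateWeightError):
            stratified_risk_ratio(df)

    def test_small_stratum_merge_policy(self):
        df = pd.concat([
            summaries_from_props({"control": [0.3, 0.2], "intervention": [0.6, 0.4]},
                                 stratum="s1"),
            summaries_from_props({"control": [0.1], "intervention": [0.2]},
                                 stratum="s2"),
        ], ignore_index=True)
        est, strata = stratified_risk_ratio(df, small_stratum="merge_smallest")
        assert len(strata) == 1 and strata[0].c1 == 3


class TestStratifiedRiskDifference:
    def test_hand_arithmetic(self, oracle_summaries):
        est, _ = stratified_risk_difference(oracle_summaries)
        assert est.point == pytest.approx(0.25, rel=1e-12)
        assert est.scale == "difference"

    def test_identical_arms_symmetric_ci(self):
        df = summaries_from_props({"control": [0.5, 0.4], "intervention": [0.5, 0.4]})
        est, _ = stratified_risk_difference(df)
        assert est.point == pytest.approx(0.0)
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_arm_swap_antisymmetry(self, oracle_summaries):
        est, _ = stratified_risk_difference(oracle_summaries)
        swapped = oracle_summaries.assign(
            arm=oracle_summaries["arm"].map(
                {"control": "intervention", "intervention": "control"})
        )
        est_sw, _ = stratified_risk_difference(swapped)
        assert est_sw.point == pytest.approx(-est.point, rel=1e-12)
        assert abs(est_sw.t_stat) == pytest.approx(abs(est.t_stat), rel=1e-12)


class TestCovariateModel:
    def test_intercept_only_fits_sample_proportion(self):
        y = np.array([1] * 12 + [0] * 18)
        model = fit_covariate_model(np.empty((30, 0)), y, terms=[])
        assert np.allclose(model.fitted, 0.4)
        assert model.converged

    def test_saturated_two_by_two_equals_crude_odds_ratio(self):
        # single binary covariate: exp(slope) must equal ad/bc
        a, b, c, d = 194, 122, 540, 668
        x = np.array([1] * (a + c) + [0] * (b + d), dtype=float)
        y = np.array([1] * a + [0] * c + [1] * b + [0] * d, dtype=float)
        model = fit_covariate_model(x[:, None], y, terms=["age_lt_35"])
        assert math.exp(model.coefficient("age_lt_35")) == pytest.approx(
            a * d / (b * c), rel=1e-9
        )

    def test_matches_statsmodels_on_multivariate_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        X = rng.normal(size=(400, 3))
        eta = 0.3 + X @ np.array([0.8, -0.5, 0.0])
        y = rng.random(400) < 1 / (1 + np.exp(-eta))
        model = fit_covariate_model(X, y.astype(float))
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        assert np.allclose(model.coefficients, ref.params, atol=1e-6)

    def test_balanced_null_covariate_has_zero_slope(self):
        x = np.array([0.0, 1.0] * 50)
        y = np.array([0.0, 0.0, 1.0, 1.0] * 25)
        model = fit_covariate_model(x[:, None], y, terms=["x"])
        assert model.coefficient("x") == pytest.approx(0.0, abs=1e-8)

    def test_separation_raises_naming_term(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()
        with pytest.raises(SeparationError, match="sep"):
            fit_covariate_model(x[:, None], y, terms=["sep"])

    def test_rank_deficiency_raises_naming_aliased_terms(self):
        x = np.linspace(0, 1, 40)
        X = np.column_stack([x, 2 * x])
        y = (x > 0.5).astype(float)
        with pytest.raises(RankDeficiencyError):
            fit_covariate_model(X, y, terms=["x", "x_twice"])

    def test_design_matrix_reference_encoding(self):
        df = pd.DataFrame({"sex": ["male", "female", "male"],
                           "age": [30, 40, 50]})
        X = build_design_matrix(df, ["sex", "age"])
        assert list(X.columns) == ["sex=male", "age"]
        assert X["sex=male"].tolist() == [1.0, 0.0, 1.0]


class TestResidualize:
    def _individuals(self, summaries):
        rows = []
        for row in summaries.itertuples():
            rows += [{"cluster_id": row.cluster_id, "y": 1}] * row.o
            rows += [{"cluster_id": row.cluster_id, "y": 0}] * (row.n - row.o)
        return pd.DataFrame(rows)

    def test_intercept_only_ratio_residual_is_p_over_pbar(self, oracle_summaries):
        ind = self._individuals(oracle_summaries)
        model = fit_covariate_model(np.empty((len(ind), 0)),
                                    ind["y"].to_numpy(), terms=[])
        out = residualize(oracle_summaries, model, ind)
        pbar = oracle_summaries["o"].sum() / oracle_summaries["n"].sum()
        assert np.allclose(out["r"], (oracle_summaries["o"] / oracle_summaries["n"]) / pbar)
        assert out["e"].sum() == pytest.approx(oracle_summaries["o"].sum())

    def test_perfect_prediction_gives_unit_ratio_zero_difference(self, oracle_summaries):
        ind = self._individuals(oracle_summaries)
        # saturated model: cluster indicator dummies reproduce observed p
        X = build_design_matrix(ind.assign(cluster=ind["cluster_id"]), ["cluster"])
        model = fit_covariate_model(X, ind["y"].to_numpy())
        out = residualize(oracle_summaries, model, ind)
        assert np.allclose(out["r"], 1.0, atol=1e-6)
        assert np.allclose(out["d"], 0.0, atol=1e-6)

    def test_ratio_residual_scale_invariance(self, oracle_summaries):
        ind = self._individuals(oracle_summaries)
        doubled = pd.concat([ind, ind], ignore_index=True)
        m1 = fit_covariate_model(np.empty((len(ind), 0)), ind["y"].to_numpy(), terms=[])
        m2 = fit_covariate_model(np.empty((len(doubled), 0)),
                                 doubled["y"].to_numpy(), terms=[])
        s2 = oracle_summaries.assign(o=2 * oracle_summaries["o"],
                                     n=2 * oracle_summaries["n"])
        r1 = residualize(oracle_summaries, m1, ind)["r"]
        r2 = residualize(s2, m2, doubled)["r"]
        assert np.allclose(r1, r2)

    def test_intercept_only_adjustment_reproduces_unadjusted(self, oracle_summaries):
        ind = self._individuals(oracle_summaries)
        model = fit_covariate_model(np.empty((len(ind), 0)),
                                    ind["y"].to_numpy(), terms=[])
        out = residualize(oracle_summaries, model, ind)
        unadj, _ = stratified_risk_ratio(oracle_summaries)
        adj, _ = stratified_risk_ratio(out, use_residuals=True)
        assert math.log(adj.point) == pytest.approx(math.log(unadj.point), abs=1e-12)
        assert adj.se == pytest.approx(unadj.se, abs=1e-12)
        unadj_d, _ = stratified_risk_difference(oracle_summaries)
        adj_d, _ = stratified_risk_difference(out, use_residuals=True)
        assert adj_d.point == pytest.approx(unadj_d.point, abs=1e-12)


class TestPairedChangeTest:
    def _frame(self, diffs, base=0.5):
        rows = []
        for i, d in enumerate(diffs):
            rows.append({"cluster_id": f"c{i}", "stratum": "s", "arm": "control",
                         "period": "baseline", "o": 0, "n": 100, "p": base})
            rows.append({"cluster_id": f"c{i}", "stratum": "s", "arm": "control",
                         "period": "endline", "o": 0, "n": 100, "p": base + d})
        return pd.DataFrame(rows)

    def test_symmetric_differences(self):
        res = paired_change_test(self._frame([0.1, -0.1]), "control")
        assert res.mean_difference == pytest.approx(0.0)
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        res = paired_change_test(self._frame([0.2, 0.2, 0.2]), "control")
        assert res.zero_variance and res.p_value is None
        assert res.mean_difference == pytest.approx(0.2)

    def test_hand_computed_t(self):
        res = paired_change_test(self._frame([0.1, 0.3]), "control")
        assert res.mean_difference == pytest.approx(0.2)
        assert res.t_stat == pytest.approx(2.0)
        assert res.df == 1
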