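import numpy as np
import pandas as pd
import pytest
from scipy import stats

from persym.analysis import (
    DegenerateDesignError,
    EffectEstimate,
    PowerSpec,
    add_tertiles,
    ancova_effect,
    mixed_other_effect,
    power_t,
    productivity_change,
    qaly_auc,
    sample_size_t,
    subgroup_forest,
    subgroup_frame,
)


def make_cohort(n, rng, effect_by=None):
    cohort = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "arm": rng.permutation(np.repeat(["control", "intervention"], n // 2)),
        "age_band": rng.choice(["<50", "50+"], n),
        "imd_band": rng.choice(["1-5", "6-10"], n),
        "sex": rng.choice(["female", "male"], n, p=[0.85, 0.15]),
        "ethnicity": rng.choice(["other", "south_asian"], n, p=[0.95, 0.05]),
        "chosen_symptom": rng.choice(["fatigue", "breathlessness", "pain", "other"], n),
    })
    return cohort


def make_outcome(cohort, rng, effect=0.0, rho=0.5, noise=1.0, visit=6):
    n = len(cohort)
    z0 = rng.standard_normal(n)
    interv = (cohort["arm"] == "intervention").to_numpy(dtype=float)
    z6 = rho * z0 + np.sqrt(1 - rho**2) * rng.standard_normal(n) * noise + effect * interv
    return pd.concat([
        pd.DataFrame({"participant_id": cohort["participant_id"], "visit_month": 0,
                      "z": z0}),
        pd.DataFrame({"participant_id": cohort["participant_id"], "visit_month": visit,
                      "z": z6}),
    ], ignore_index=True)


def oracle_normal_equations(outcome_long, cohort, visit, alpha=0.05):
    """Independent least-squares route: explicit normal equations."""
    base = outcome_long[outcome_long["visit_month"] == 0][["participant_id", "z"]]
    fup = outcome_long[outcome_long["visit_month"] == visit][["participant_id", "z"]]
    df = cohort.merge(base.rename(columns={"z": "z0"}), on="participant_id")
    df = df.merge(fup.rename(columns={"z": "z6"}), on="participant_id")
    cols = [np.ones(len(df)), (df["arm"] == "intervention").to_numpy(float)]
    names = ["intercept", "group"]
    for cov in ("age_band", "imd_band", "sex", "ethnicity", "chosen_symptom"):
        levels = sorted(df[cov].unique())[1:]
        for lv in levels:
            cols.append((df[cov] == lv).to_numpy(float))
            names.append(f"{cov}[{lv}]")
    cols.append(df["z0"].to_numpy())
    names.append("baseline")
    X = np.column_stack(cols)
    y = df["z6"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    j = names.index("group")
    est, se = beta[j], np.sqrt(cov_beta[j, j])
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    return est, se, est - tcrit * se, est + tcrit * se


class TestAncova:
    def test_noiseless_additive_effect_recovered_exactly(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(40, rng)
        z0 = rng.standard_normal(40)
        interv = (cohort["arm"] == "intervention").to_numpy(float)
        outcome = pd.concat([
            pd.DataFrame({"participant_id": cohort["participant_id"],
                          "visit_month": 0, "z": z0}),
            pd.DataFrame({"participant_id": cohort["participant_id"],
                          "visit_month": 6, "z": z0 - 0.5 * interv}),
        ])
        eff = ancova_effect(outcome, cohort, 6)
        assert eff.estimate == pytest.approx(-0.5, abs=1e-10)
        assert eff.ci_high - eff.ci_low == pytest.approx(0.0, abs=1e-7)

    def test_matches_normal_equations_oracle_n20(self):
        rng = np.random.default_rng(42)
        cohort = make_cohort(20, rng)
        outcome = make_outcome(cohort, rng, effect=-0.4)
        eff = ancova_effect(outcome, cohort, 6)
        est, se, lo, hi = oracle_normal_equations(outcome, cohort, 6)
        assert eff.estimate == pytest.approx(est, abs=1e-8)
        assert eff.se == pytest.approx(se, abs=1e-8)
        assert eff.ci_low == pytest.approx(lo, abs=1e-8)
        assert eff.ci_high == pytest.approx(hi, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_oracle_agreement_across_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        cohort = make_cohort(60, rng)
        outcome = make_outcome(cohort, rng, effect=rng.normal())
        eff = ancova_effect(outcome, cohort, 6)
        est, se, _, _ = oracle_normal_equations(outcome, cohort, 6)
        assert eff.estimate == pytest.approx(est, abs=1e-8)
        assert eff.se == pytest.approx(se, abs=1e-8)

    def test_collinear_design_names_covariate(self):
        rng = np.random.default_rng(3)
        cohort = make_cohort(30, rng)
        cohort["imd_band"] = cohort["age_band"].map({"<50": "1-5", "50+": "6-10"})
        outcome = make_outcome(cohort, rng)
        with pytest.raises(DegenerateDesignError, match="imd_band|age_band"):
            ancova_effect(outcome, cohort, 6)

    def test_empty_visit_errors(self):
        rng = np.random.default_rng(4)
        cohort = make_cohort(20, rng)
        outcome = make_outcome(cohort, rng)
        with pytest.raises(ValueError, match="no analyzable rows"):
            ancova_effect(outcome, cohort, 12)

    def test_complete_case_excludes_missing(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort(40, rng)
        outcome = make_outcome(cohort, rng)
        outcome.loc[(outcome["visit_month"] == 6).to_numpy().nonzero()[0][:5], "z"] = np.nan
        eff = ancova_effect(outcome, cohort, 6)
        assert eff.n_analyzed == 35

    def test_ci_brackets_estimate_invariant(self):
        with pytest.raises(ValueError):
            EffectEstimate("z", 6, estimate=1.0, se=0.1, ci_low=1.1, ci_high=1.3,
                           p_value=0.5, n_analyzed=10)


class TestMixedOther:
    def _other_data(self, rng, n=60, per=3, effect=-0.8, between=1.0, within=0.5):
        cohort = make_cohort(n, rng)
        interv = (cohort["arm"] == "intervention").to_numpy(float)
        rows = []
        labels = [f"sym{j}" for j in range(per)]
        u = rng.standard_normal(n) * between
        for i in range(n):
            for j in range(per):
                v0 = 6 + u[i] + rng.standard_normal() * within
                v6 = 6 + u[i] + rng.standard_normal() * within + effect * interv[i]
                rows.append((cohort["participant_id"].iloc[i], 0, labels[j], v0))
                rows.append((cohort["participant_id"].iloc[i], 6, labels[j], v6))
        return cohort, pd.DataFrame(rows, columns=["participant_id", "visit_month",
                                                   "symptom_label", "vas"])

    def test_single_row_collapses_to_ancova(self):
        rng = np.random.default_rng(10)
        cohort, other = self._other_data(rng, per=1)
        mixed = mixed_other_effect(other, cohort, 6)
        tidy = other.rename(columns={"vas": "z"})
        ols = ancova_effect(tidy, cohort, 6, outcome="z")
        assert mixed.estimate == pytest.approx(ols.estimate, abs=1e-6)
        assert mixed.se == pytest.approx(ols.se, abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        ests = []
        for _ in range(60):
            cohort, other = self._other_data(rng, n=180, per=3, effect=-0.8)
            ests.append(mixed_other_effect(other, cohort, 6).estimate)
        assert np.mean(ests) == pytest.approx(-0.8, abs=0.1)

    def test_zero_within_variance_boundary(self):
        rng = np.random.default_rng(12)
        cohort, other = self._other_data(rng, n=40, per=2, within=0.0, effect=-0.5)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = mixed_other_effect(other, cohort, 6)
        assert np.isfinite(eff.estimate)
        assert eff.estimate == pytest.approx(-0.5, abs=0.5)


class TestSubgroups:
    def test_null_interaction_p_uniform(self):
        rng = np.random.default_rng(20)
        pvals = []
        for _ in range(200):
            cohort = make_cohort(80, rng)
            outcome = make_outcome(cohort, rng, effect=-0.4)  # homogeneous
            res = subgroup_forest(outcome, cohort, 6, {"sex": "sex"})
            pvals.append(res[0].interaction_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_sex_specific_effect_detected(self):
        rng = np.random.default_rng(21)
        hits = 0
        reps = 60
        for _ in range(reps):
            cohort = make_cohort(234, rng)
            # balanced sexes so the interaction contrast is identifiable at
            # the stated power
            cohort["sex"] = rng.choice(["female", "male"], len(cohort))
            outcome = make_outcome(cohort, rng, effect=0.0)
            female = cohort["sex"].eq("female")
            interv = cohort["arm"].eq("intervention")
            idx = outcome["visit_month"].eq(6).to_numpy()
            boost = (female & interv).reindex(range(len(cohort))).to_numpy(float) * -0.7
            outcome.loc[idx, "z"] = outcome.loc[idx, "z"].to_numpy() + boost
            res = subgroup_forest(outcome, cohort, 6, {"sex": "sex"})
            if res and res[0].interaction_p < 0.05:
                hits += 1
        assert hits / reps > 0.8

    def test_single_level_variable_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(22)
        cohort = make_cohort(40, rng)
        cohort["region"] = "north"
        outcome = make_outcome(cohort, rng)
        with caplog.at_level("WARNING", logger="persym.analysis"):
            res = subgroup_forest(outcome, cohort, 6, {"region": "region"})
        assert res == []
        assert "region" in caplog.text

    def test_frame_shape(self):
        rng = np.random.default_rng(23)
        cohort = make_cohort(60, rng)
        outcome = make_outcome(cohort, rng, effect=-0.3)
        frame = subgroup_frame(subgroup_forest(outcome, cohort, 6, {"sex": "sex"}))
        assert set(frame.columns) >= {"variable", "level", "estimate", "ci_low",
                                      "ci_high", "interaction_p"}
        assert frame["interaction_p"].nunique() == 1  # one p per variable

    def test_tertiles(self):
        t = add_tertiles(pd.Series(range(30)), "age")
        assert t.value_counts().tolist() == [10, 10, 10]


class TestPower:
    def test_sample_size_headline(self):
        spec = PowerSpec(delta=0.5, power=0.90, alpha=0.05)
        assert sample_size_t(spec) == 86

    def test_sample_size_monotone_in_delta(self):
        n_small = sample_size_t(PowerSpec(delta=1.0, power=0.90, alpha=0.05))
        assert n_small < 86 / 2 + 1

    def test_normal_approximation_lower_bound(self):
        # 2(z_.975+z_.9)^2/delta^2 = 84.06; t correction adds at least one
        za, zb = stats.norm.ppf(0.975), stats.norm.ppf(0.9)
        approx = 2 * (za + zb) ** 2 / 0.5**2
        assert approx == pytest.approx(84.06, abs=0.01)
        assert sample_size_t(PowerSpec(delta=0.5, power=0.90)) >= 85

    def test_zero_delta_unattainable(self):
        with pytest.raises(ValueError):
            sample_size_t(PowerSpec(delta=0.0, power=0.9))

    def test_power_headline(self):
        spec = PowerSpec(delta=0.5, n1=97, n2=117, alpha=0.05)
        assert round(power_t(spec) * 100, 1) == 95.2

    def test_null_identity(self):
        assert power_t(PowerSpec(delta=0.0, n1=10, n2=10)) == pytest.approx(0.05, abs=1e-6)

    def test_inverse_consistency(self):
        assert power_t(PowerSpec(delta=0.5, n1=86, n2=86)) >= 0.90

    def test_round_trip(self):
        for delta, target in [(0.4, 0.8), (0.5, 0.9), (0.8, 0.95)]:
            n = sample_size_t(PowerSpec(delta=delta, power=target))
            assert power_t(PowerSpec(delta=delta, n1=n, n2=n)) >= target
            assert power_t(PowerSpec(delta=delta, n1=n - 1, n2=n - 1)) < target

    def test_power_monotone(self):
        p1 = power_t(PowerSpec(delta=0.5, n1=50, n2=50))
        p2 = power_t(PowerSpec(delta=0.5, n1=60, n2=50))
        p3 = power_t(PowerSpec(delta=0.6, n1=50, n2=50))
        assert p2 > p1 and p3 > p1


class TestQALY:
    def test_constant_utility(self):
        assert qaly_auc([1.0, 1.0], [0, 6]) == pytest.approx(0.5)

    def test_hand_trapezoid(self):
        assert qaly_auc([0.6, 0.8], [0, 6]) == pytest.approx(0.35)

    def test_single_visit_errors(self):
        with pytest.raises(ValueError):
            qaly_auc([0.7], [0])

    def test_unordered_times_error(self):
        with pytest.raises(ValueError):
            qaly_auc([0.5, 0.6], [6, 0])

    def test_linear_in_utilities(self):
        u = [0.3, 0.5, 0.7]
        t = [0, 3, 6]
        assert qaly_auc([2 * x for x in u], t) == pytest.approx(2 * qaly_auc(u, t))

    def test_additive_over_intervals(self):
        u = [0.3, 0.5, 0.7]
        assert qaly_auc(u, [0, 3, 6]) == pytest.approx(
            qaly_auc(u[:2], [0, 3]) + qaly_auc(u[1:], [3, 6]))


class TestProductivity:
    def _hours(self, cohort, delta_by_arm, rng):
        n = len(cohort)
        h0 = rng.uniform(5, 20, n).round(1)
        delta = cohort["arm"].map(delta_by_arm).to_numpy()
        return pd.concat([
            pd.DataFrame({"participant_id": cohort["participant_id"], "visit_month": 0,
                          "work_hours_missed": h0}),
            pd.DataFrame({"participant_id": cohort["participant_id"], "visit_month": 6,
                          "work_hours_missed": np.maximum(h0 + delta, 0)}),
        ], ignore_index=True)

    def test_all_zero_hours(self):
        rng = np.random.default_rng(30)
        cohort = make_cohort(30, rng)
        hours = self._hours(cohort, {"control": 0.0, "intervention": 0.0}, rng)
        hours["work_hours_missed"] = 0.0
        summary, eff = productivity_change(hours, cohort, 6)
        assert (summary["mean_change"] == 0).all()
        assert eff.estimate == pytest.approx(0.0, abs=1e-10)

    def test_constructed_difference(self):
        rng = np.random.default_rng(31)
        cohort = make_cohort(30, rng)
        hours = self._hours(cohort, {"control": -2.0, "intervention": -3.0}, rng)
        summary, eff = productivity_change(hours, cohort, 6)
        assert abs(eff.estimate) == pytest.approx(1.0, abs=1e-8)
        assert eff.estimate < 0  # intervention reduced hours more

    def test_negative_hours_rejected(self):
        rng = np.random.default_rng(32)
        cohort = make_cohort(10, rng)
        hours = self._hours(cohort, {"control": 0.0, "intervention": 0.0}, rng)
        hours.loc[0, "work_hours_missed"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            productivity_change(hours, cohort, 6)

    def test_missing_followup_counted_in_attrition(self):
        rng = np.random.default_rng(33)
        cohort = make_cohort(30, rng)
        hours = self._hours(cohort, {"control": -2.0, "intervention": -3.0}, rng)
        drop = hours[(hours["visit_month"] == 6)].index[:4]
        hours.loc[drop, "work_hours_missed"] = np.nan
        summary, eff = productivity_change(hours, cohort, 6)
        assert eff.n_analyzed == 26
        assert summary["n_missing"].sum() == 4
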