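"""Association harness: Cox/logistic per 1 s.d., BH-FDR, matching, AUC, incidence."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from organclock.associations import (
    add_fdr,
    bh_fdr,
    check_proportional_hazards,
    compare_auc,
    cumulative_incidence,
    define_multimorbidity,
    define_transitions,
    fit_cox,
    fit_logistic,
    lifestyle_category,
    match_controls,
    relative_contribution,
)


def _surv_frame(rng, n=1500, beta=0.0, baseline=0.05, horizon=13.0):
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (baseline * np.exp(beta * x)))
    return pd.DataFrame(
        {"time": np.minimum(t, horizon), "event": (t <= horizon).astype(int), "x": x}
    )


class TestCox:
    def test_null_exposure_gives_hr_near_one(self, rng):
        res = fit_cox(_surv_frame(rng, n=2000), "null", "x")
        assert abs(np.log(res.effect)) < 0.1
        assert res.ci_low < res.effect < res.ci_high

    def test_per_sd_reporting_invariant_to_rescaling(self, rng):
        df = _surv_frame(rng, n=800, beta=0.3)
        r1 = fit_cox(df, "o", "x")
        df2 = df.assign(x=df["x"] * 37.2)
        r2 = fit_cox(df2, "o", "x")
        assert r1.effect == pytest.approx(r2.effect, rel=1e-6)

    def test_too_few_events_flagged(self, rng):
        df = _surv_frame(rng, n=40, baseline=0.001)
        res = fit_cox(df, "rare", "x")
        assert res.flagged and res.q is None

    def test_generator_effect_recovered(self, rng):
        df = _surv_frame(rng, n=4000, beta=np.log(1.5), baseline=0.028)
        res = fit_cox(df, "o", "x")
        # exposure already unit-s.d.: per-1-s.d. log HR should match the generator
        assert abs(np.log(res.effect) - np.log(1.5)) < 0.08


class TestLogistic:
    def test_effect_recovery_and_label_inversion_symmetry(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.5 * x)))
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"label": y, "x": x})
        res = fit_logistic(df, "o", "x")
        assert abs(np.log(res.effect) - 0.5) < 0.1
        inv = fit_logistic(df.assign(label=1 - df["label"]), "o", "x")
        assert inv.effect == pytest.approx(1.0 / res.effect, rel=1e-4)

    def test_separation_is_flagged(self):
        df = pd.DataFrame({"label": [0] * 20 + [1] * 20, "x": list(range(40))})
        res = fit_logistic(df, "sep", "x")
        assert res.flagged

    def test_single_class_rejected(self):
        df = pd.DataFrame({"label": [1] * 10, "x": range(10)})
        with pytest.raises(ValueError):
            fit_logistic(df, "o", "x")


class TestFDR:
    def test_step_up_oracle_small(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_flat_case_and_elementwise_bounds(self, rng):
        p = np.full(7, 0.2)
        np.testing.assert_allclose(bh_fdr(p), p)
        p = rng.random(100)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            q = bh_fdr(p)
            # brute-force step-up oracle
            m = len(p)
            order = np.argsort(p, kind="stable")
            brute = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
                ]
                brute[idx] = min(1.0, min(candidates))
            np.testing.assert_allclose(q, brute, atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestContribution:
    def _results(self, zs, qs):
        from organclock.associations import AssociationResult

        return [
            AssociationResult("o", f"e{i}", 1.2, 1.0, 1.4, z, 0.01, 100, q=q)
            for i, (z, q) in enumerate(zip(zs, qs))
        ]

    def test_weights_scale_to_one(self):
        w = relative_contribution(self._results([6, 3, 1], [0.01, 0.01, 0.01]))
        np.testing.assert_allclose(sorted(w, reverse=True), [0.6, 0.3, 0.1])

    def test_singleton_and_empty(self):
        w = relative_contribution(self._results([4], [0.001]))
        assert w.iloc[0] == 1.0
        empty = relative_contribution(self._results([4, 2], [0.5, 0.9]))
        assert empty.empty and not empty.isna().any()


class TestTransitions:
    def test_mci_thresholds_inclusive_and_distress_cutoff(self, rng):
        n = 500
        idx = pd.RangeIndex(n)
        # reference stats exactly (0, 1) by construction
        base = pd.Series(rng.standard_normal(n), index=idx)
        base = (base - base.mean()) / base.std(ddof=1)
        followup = base.copy()
        followup.iloc[0] = -1.6
        followup.iloc[1] = -1.4
        edu = pd.Series("low", index=idx)
        distress = pd.Series(5.0, index=idx)
        distress.iloc[2] = 6.0
        out = define_transitions(base, followup, edu, distress)
        assert out["mci_followup"].iloc[0] == 1.0  # −1.6 ≤ −1.5
        assert out["mci_followup"].iloc[1] == 0.0  # −1.4 above the cut
        assert out["distress_baseline"].iloc[2] == 1.0  # ≥ 6 inclusive
        assert out["distress_baseline"].iloc[3] == 0.0

    def test_small_stratum_skipped_with_warning(self):
        idx = pd.RangeIndex(4)
        base = pd.Series([0.0, 0.1, -0.1, 0.2], index=idx)
        edu = pd.Series(["a", "a", "a", "rare"], index=idx)
        with pytest.warns(UserWarning, match="rare"):
            out = define_transitions(base, base, edu, pd.Series(0.0, index=idx))
        assert np.isnan(out["mci_baseline"].iloc[3])


class TestMultimorbidity:
    def test_category_rules(self):
        incident = pd.DataFrame(
            {
                "stroke": [1, 1, 0],
                "diabetes": [1, 0, 0],
                "depression": [0, 1, 0],
            },
            index=["two_physical", "one_each", "none"],
        )
        cats = {"stroke": "physical", "diabetes": "physical", "depression": "neuropsychiatric"}
        out = define_multimorbidity(incident, cats)
        assert out.at["two_physical", "physical_multimorbid"] == 1
        assert out.at["one_each", "physical_multimorbid"] == 0
        assert out.at["one_each", "neuropsychiatric_multimorbid"] == 0
        assert out.at["one_each", "combined_multimorbid"] == 1
        assert out.loc["none"].sum() == 0

    def test_unmapped_disease_rejected(self):
        with pytest.raises(ValueError):
            define_multimorbidity(pd.DataFrame({"x": [1]}), {})


class TestMatching:
    def _people(self, rng, n):
        return pd.DataFrame(
            {"age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n)},
            index=[f"p{i}" for i in range(n)],
        )

    def test_constraints_ratio_and_no_reuse(self, rng):
        pool = self._people(rng, 3000)
        cases = self._people(rng, 30)
        cases.index = [f"c{i}" for i in range(30)]
        matches, unmatched = match_controls(cases, pool, seed=1)
        assert not unmatched
        per_case = matches.groupby("case_id").size()
        assert (per_case == 5).all()
        assert matches["control_id"].is_unique
        merged = matches.merge(cases, left_on="case_id", right_index=True).merge(
            pool, left_on="control_id", right_index=True, suffixes=("_case", "_ctl")
        )
        assert ((merged["age_case"] - merged["age_ctl"]).abs() <= 2).all()
        assert (merged["sex_case"] == merged["sex_ctl"]).all()

    def test_empty_pool_and_unmatchable_case(self, rng):
        with pytest.raises(ValueError):
            match_controls(self._people(rng, 3), self._people(rng, 0).iloc[:0])
        pool = self._people(rng, 50)
        case = pd.DataFrame({"age": [120.0], "sex": [0]}, index=["c0"])
        matches, unmatched = match_controls(case, pool, seed=0)
        assert unmatched == ["c0"] and matches.empty


class TestAUC:
    def test_perfect_separation_and_noise(self, rng):
        n = 2000
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({"y": y, "perfect": y.astype(float), "noise": rng.standard_normal(n)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs, _ = compare_auc(df, "y", {"a": ["perfect"], "b": ["noise"]}, n_boot=20, seed=0)
        assert aucs["a"] == pytest.approx(1.0)
        assert abs(aucs["b"] - 0.5) < 0.03

    def test_binormal_closed_form(self, rng):
        n, delta = 5000, 1.0
        y = rng.integers(0, 2, n)
        df = pd.DataFrame({"y": y, "x": delta * y + rng.standard_normal(n)})
        aucs, _ = compare_auc(df, "y", {"m": ["x"]}, n_boot=10, seed=0)
        assert abs(aucs["m"] - stats.norm.cdf(delta / np.sqrt(2))) < 0.02

    def test_better_model_beats_noise_with_small_p(self, rng):
        n = 1500
        y = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {"y": y, "good": 1.5 * y + rng.standard_normal(n), "noise": rng.standard_normal(n)}
        )
        _, pairs = compare_auc(df, "y", {"good": ["good"], "noise": ["noise"]}, n_boot=400, seed=0)
        assert pairs["p"].iloc[0] < 0.05
        assert pairs["diff"].iloc[0] > 0


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self):
        tab = pd.DataFrame({"time": [5.0, 6.0, 7.0], "event": [0, 0, 0]}, index=list("abc"))
        curves = cumulative_incidence(tab, pd.Series(["g"] * 3, index=tab.index))
        assert (curves["g"]["cum_incidence"] == 0).all()

    def test_all_events_distinct_times_step_by_one_over_n(self):
        n = 8
        tab = pd.DataFrame(
            {"time": np.arange(1, n + 1, dtype=float), "event": 1}, index=range(n)
        )
        curves = cumulative_incidence(tab, pd.Series(["g"] * n, index=tab.index))
        curve = curves["g"]
        steps = np.diff(curve["cum_incidence"].to_numpy())
        # KM with no censoring steps by exactly 1/n at every event time
        np.testing.assert_allclose(steps[steps > 0], 1.0 / n, atol=1e-12)

    def test_higher_hazard_group_dominates(self, rng):
        n = 1000
        g = np.repeat(["lo", "hi"], n // 2)
        lam = np.where(g == "hi", 0.15, 0.05)
        t = rng.exponential(1 / lam)
        tab = pd.DataFrame(
            {"time": np.minimum(t, 13.0), "event": (t <= 13.0).astype(int)}, index=range(n)
        )
        curves = cumulative_incidence(tab, pd.Series(g, index=tab.index))
        common = np.linspace(1, 12, 20)
        hi = np.interp(common, curves["hi"]["time"], curves["hi"]["cum_incidence"])
        lo = np.interp(common, curves["lo"]["time"], curves["lo"]["cum_incidence"])
        assert (hi >= lo).all()

    def test_empty_group_skipped(self, rng):
        tab = pd.DataFrame({"time": [1.0], "event": [1]}, index=["a"])
        groups = pd.Series(pd.Categorical(["g1"], categories=["g1", "g2"]), index=["a"])
        with pytest.warns(UserWarning, match="empty"):
            curves = cumulative_incidence(tab, groups)
        assert set(curves) == {"g1"}


class TestLifestyleAndPH:
    def test_lifestyle_categories(self):
        counts = pd.Series([0, 2, 3, 5, 6, 9])
        cats = lifestyle_category(counts)
        assert cats.tolist() == [
            "favorable", "favorable", "intermediate", "intermediate",
            "unfavorable", "unfavorable",
        ]
        with pytest.raises(ValueError):
            lifestyle_category(pd.Series([10]))

    def test_schoenfeld_flags_time_varying_effect(self, rng):
        n = 3000
        x = rng.standard_normal(n)
        # effect that decays over time violates proportional hazards
        u = rng.random(n)
        t_early = rng.exponential(1 / (0.3 * np.exp(1.2 * x)))
        t_late = 5 + rng.exponential(1 / 0.3, n)
        t = np.where(u < 0.5, t_early, t_late)
        df = pd.DataFrame({"time": np.minimum(t, 13.0), "event": (t <= 13.0).astype(int), "x": x})
        p = check_proportional_hazards(df, "x")
        assert p < 0.05


def test_fdr_family_bookkeeping_excludes_flagged(rng):
    from organclock.associations import AssociationResult

    fam = [
        AssociationResult("o", "a", 1.5, 1.2, 1.8, 3.0, 0.01, 50),
        AssociationResult("o", "b", 1.1, 0.9, 1.3, 1.0, 0.30, 50),
        AssociationResult("o", "c", np.nan, np.nan, np.nan, np.nan, np.nan, 2, flagged=True),
    ]
    add_fdr(fam)
    assert fam[0].q == pytest.approx(0.02)
    assert fam[2].q is None
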