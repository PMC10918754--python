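"""Moderated regressions, FDR, simple slopes, polynomial age curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import brainvar as bv
from brainvar.cohort import emulated_measured_variability
from brainvar.labels import FACTORS, NETWORKS
from brainvar.lifespan import PREDICTORS


def _toy_inputs(rng, n=300, b_delta=0.5, b_int=0.02):
    """Scores/variability/phenotypes with a known DMN-by-age effect."""
    sid = [f"s{i}" for i in range(n)]
    age = rng.uniform(6, 85, n)
    delta = rng.normal(0.5, 0.5, n)
    pheno = pd.DataFrame({
        "subject_id": sid, "age": age,
        "sex": rng.choice(["F", "M"], n),
        "handedness": rng.choice(["R", "L"], n, p=[0.9, 0.1]),
        "education_years": rng.uniform(4, 20, n),
    })
    agec = age - age.mean()
    y = b_delta * delta + b_int * delta * agec + rng.normal(0, 1, n)
    scores = pd.DataFrame({"subject_id": sid, "cognitive_flexibility": y})
    var = pd.DataFrame({"subject_id": sid, "DMN": delta})
    return scores, var, pheno


class TestFitModel:
    def test_recovers_planted_coefficients(self, rng):
        scores, var, pheno = _toy_inputs(rng, n=4000)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN", include_interaction=True)
        res = bv.fit_model(ms, scores, var, pheno)
        assert res.terms.loc["DMN", "b"] == pytest.approx(0.5, abs=0.15)
        assert res.terms.loc["DMN:age_c", "b"] == pytest.approx(0.02, abs=0.006)

    def test_beta_equals_zscored_refit_for_main_model(self, rng):
        scores, var, pheno = _toy_inputs(rng)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN")
        res = bv.fit_model(ms, scores, var, pheno)
        merged = scores.merge(var).merge(pheno)
        y = merged["cognitive_flexibility"]
        yz = (y - y.mean()) / y.std(ddof=1)
        xz = pd.DataFrame({"const": 1.0}, index=merged.index)
        for col, raw in (("DMN", merged["DMN"]),
                         ("sex_female", (merged["sex"] == "F").astype(float)),
                         ("hand_left", (merged["handedness"] == "L").astype(float)),
                         ("education_years", merged["education_years"])):
            xz[col] = (raw - raw.mean()) / raw.std(ddof=1)
        ref = sm.OLS(yz, xz).fit()
        for term in ("DMN", "sex_female", "hand_left", "education_years"):
            assert res.terms.loc[term, "beta"] == pytest.approx(
                ref.params[term], abs=1e-10)

    def test_interaction_coefficient_invariant_to_centering(self, rng):
        scores, var, pheno = _toy_inputs(rng)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN", include_interaction=True)
        res = bv.fit_model(ms, scores, var, pheno)
        merged = scores.merge(var).merge(pheno)
        for center in (0.0, 45.5, 70.0):
            ac = merged["age"] - center
            x = pd.DataFrame({
                "const": 1.0, "DMN": merged["DMN"], "age_c": ac,
                "DMN:age_c": merged["DMN"] * ac,
                "sex_female": (merged["sex"] == "F").astype(float),
                "hand_left": (merged["handedness"] == "L").astype(float),
                "education_years": merged["education_years"]})
            ref = sm.OLS(merged["cognitive_flexibility"], x).fit()
            assert ref.params["DMN:age_c"] == pytest.approx(
                res.terms.loc["DMN:age_c", "b"], abs=1e-10)

    def test_zero_variance_predictor_rejected(self, rng):
        scores, var, pheno = _toy_inputs(rng)
        var["DMN"] = 0.7
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN")
        with pytest.raises(ValueError, match="zero variance"):
            bv.fit_model(ms, scores, var, pheno)

    def test_collinear_design_rejected_naming_columns(self, rng):
        scores, var, pheno = _toy_inputs(rng)
        pheno["education_years"] = 2.0 * var["DMN"].to_numpy()
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN")
        with pytest.raises(ValueError, match="rank deficient"):
            bv.fit_model(ms, scores, var, pheno)

    def test_too_few_cases_rejected(self, rng):
        scores, var, pheno = _toy_inputs(rng, n=10)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN")
        with pytest.raises(ValueError, match="complete cases"):
            bv.fit_model(ms, scores, var, pheno)


class TestFdr:
    def test_worked_example(self):
        # BH thresholds at q* = 0.05 for m = 4: 0.0125, 0.025, 0.0375, 0.05
        q = bv.fdr_adjust([0.01, 0.02, 0.04, 0.5])
        assert (q < 0.05).sum() == 2

    def test_all_equal_p_stay_equal(self):
        q = bv.fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_single_test_unchanged(self):
        assert bv.fdr_adjust([0.031])[0] == pytest.approx(0.031)

    def test_empty_family(self):
        assert len(bv.fdr_adjust([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bv.fdr_adjust([0.5, 1.5])

    def test_matches_brute_force_step_up(self, rng):
        # brute force: reject the largest k with p_(k) <= alpha k / m;
        # q <= alpha must select exactly that set, for every alpha
        for _ in range(200):
            m = rng.integers(1, 11)
            p = np.round(rng.random(m), 3)
            q = bv.fdr_adjust(p)
            order = np.argsort(p)
            for alpha in (0.01, 0.05, 0.1, 0.25, 0.5, 0.9):
                ps = p[order]
                ks = np.nonzero(ps <= alpha * np.arange(1, m + 1) / m)[0]
                n_reject = 0 if len(ks) == 0 else ks[-1] + 1
                assert (q <= alpha).sum() == n_reject


class TestSimpleSlopes:
    def _interaction_result(self, rng, n=1000):
        scores, var, pheno = _toy_inputs(rng, n=n)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN", include_interaction=True)
        return bv.fit_model(ms, scores, var, pheno), scores, var, pheno

    def test_linear_identity(self, rng):
        res, *_ = self._interaction_result(rng)
        b_d = res.terms.loc["DMN", "b"]
        b_i = res.terms.loc["DMN:age_c", "b"]
        ss = bv.simple_slopes(res, ages=[res.age_mean + 20.0])
        assert ss["slope"].iloc[0] == pytest.approx(b_d + 20.0 * b_i, abs=1e-12)

    def test_slope_at_centering_age_equals_main_coefficient(self, rng):
        res, *_ = self._interaction_result(rng)
        ss = bv.simple_slopes(res, ages=[res.age_mean])
        assert ss["slope"].iloc[0] == pytest.approx(
            res.terms.loc["DMN", "b"], abs=1e-12)
        assert ss["se"].iloc[0] == pytest.approx(
            res.terms.loc["DMN", "se"], abs=1e-12)

    def test_delta_method_matches_recentring_refit(self, rng):
        res, scores, var, pheno = self._interaction_result(rng)
        merged = scores.merge(var).merge(pheno)
        for probe in (13.17, 27.01, 50.09, 69.42):
            ss = bv.simple_slopes(res, ages=[probe])
            ac = merged["age"] - probe
            x = pd.DataFrame({
                "const": 1.0, "DMN": merged["DMN"], "age_c": ac,
                "DMN:age_c": merged["DMN"] * ac,
                "sex_female": (merged["sex"] == "F").astype(float),
                "hand_left": (merged["handedness"] == "L").astype(float),
                "education_years": merged["education_years"]})
            ref = sm.OLS(merged["cognitive_flexibility"], x).fit()
            assert ss["slope"].iloc[0] == pytest.approx(ref.params["DMN"],
                                                        abs=1e-10)
            assert ss["se"].iloc[0] == pytest.approx(ref.bse["DMN"], abs=1e-10)

    def test_requires_interaction_model(self, rng):
        scores, var, pheno = _toy_inputs(rng)
        ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                               predictor="DMN")
        res = bv.fit_model(ms, scores, var, pheno)
        with pytest.raises(ValueError, match="interaction"):
            bv.simple_slopes(res)


class TestAgePolynomial:
    def _pheno(self, rng, n=724):
        sid = [f"s{i}" for i in range(n)]
        return pd.DataFrame({"subject_id": sid,
                             "age": rng.uniform(6, 85, n)})

    def test_quadratic_peak_recovery(self, rng):
        pheno = self._pheno(rng)
        age = pheno["age"].to_numpy()
        y = -0.001 * (age - 45.0) ** 2 + rng.normal(0, 0.3, len(age))
        scores = pd.DataFrame({"subject_id": pheno["subject_id"],
                               "cognitive_flexibility": y})
        out = bv.age_polynomial(scores, pheno, degree=2)
        assert out["cognitive_flexibility"]["peak_age"] == pytest.approx(
            45.0, abs=2.0)

    def test_linear_noiseless_r_squared_one(self, rng):
        pheno = self._pheno(rng, n=100)
        scores = pd.DataFrame({
            "subject_id": pheno["subject_id"],
            "processing_speed": 0.02 * pheno["age"] - 1.0})
        out = bv.age_polynomial(scores, pheno, degree=1)
        assert out["processing_speed"]["r_squared"] == pytest.approx(1.0)

    def test_null_quadratic_rarely_significant(self, rng):
        # linear generative curve: the quadratic term should be ~0 and its
        # |t| < 2 in at least 90% of null replicates
        hits = 0
        reps = 60
        for _ in range(reps):
            pheno = self._pheno(rng, n=300)
            age = pheno["age"].to_numpy()
            y = 0.01 * age + rng.normal(0, 0.5, 300)
            scores = pd.DataFrame({"subject_id": pheno["subject_id"],
                                   "working_memory": y})
            out = bv.age_polynomial(scores, pheno, degree=2)
            coef = out["working_memory"]["coefficients"]
            ac = age - age.mean()
            x = sm.add_constant(np.column_stack([ac, ac ** 2]))
            fit = sm.OLS(y, x).fit()
            assert fit.params[2] == pytest.approx(coef[2], abs=1e-8)
            hits += abs(fit.tvalues[2]) < 2
        assert hits / reps >= 0.9

    def test_degree_must_be_below_n(self, rng):
        pheno = self._pheno(rng, n=5)
        scores = pd.DataFrame({"subject_id": pheno["subject_id"],
                               "working_memory": np.arange(5.0)})
        with pytest.raises(ValueError, match="degree"):
            bv.age_polynomial(scores, pheno, degree=5)


class TestModelFamily:
    def test_48_models_with_families_of_six(self):
        spec = bv.CohortSpec(n_subjects=250, seed=31)
        pheno, truth = bv.generate_phenotypes(spec)
        bv.generate_task_scores(spec, truth)
        var = emulated_measured_variability(spec, truth)
        fam = bv.run_model_family(truth.factors, var, pheno)
        focal = fam.table[fam.table.focal]
        assert len(focal) == len(FACTORS) * len(PREDICTORS) * 2 == 48
        by_family = focal.groupby(["outcome", "effect_type"]).size()
        assert (by_family == 6).all()
        assert focal["q"].notna().all()
        assert (focal["q"] >= focal["p"] - 1e-12).all()

    def test_gamma_interaction_recovery_across_replicates(self):
        # single planted interaction, correctly specified model: the mean
        # estimate over replicates must sit within 2 MC SEs of truth
        gamma = 0.12
        est = []
        for rep in range(200):
            spec = bv.CohortSpec(
                n_subjects=724, seed=50_000 + rep,
                gamma_main={},
                gamma_interaction={("cognitive_flexibility", "DMN"): gamma},
                factor_age_curve={})
            pheno, truth = bv.generate_phenotypes(spec)
            bv.generate_task_scores(spec, truth)
            # exact generative targets: the estimand is gamma itself
            var = truth.subjects[["subject_id"]
                                 + [f"delta_adj_{n}" for n in NETWORKS]]
            var = var.rename(columns={f"delta_adj_{n}": n for n in NETWORKS})
            ms = bv.ModerationSpec(outcome="cognitive_flexibility",
                                   predictor="DMN", include_interaction=True)
            res = bv.fit_model(ms, truth.factors, var, pheno)
            est.append(res.terms.loc["DMN:age_c", "b"])
        mean = np.mean(est)
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - gamma) < 2 * mc_se
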