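"""Robust-design likelihood, fitting, and multimodel inference."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import spotpatterns as sp
from spotpatterns import cmr
from spotpatterns.cmr import _ModelDesign


def make_data(histories, schedule, **kw):
    hist = np.atleast_2d(np.asarray(histories, dtype=np.uint8))
    return cmr.EncounterHistorySet(hist, np.ones(len(hist), dtype=int),
                                   schedule, **kw)


def simple_spec(**kw):
    """Constant-parameter spec used for closed-form checks."""
    base = dict(s_age=False, gamma_age=False, p_time=False, c_time=False)
    base.update(kw)
    return cmr.SurvivalModelSpec(name="test", **base)


def beta_for(design, **values):
    """Parameter vector from a name → value mapping (defaults 0)."""
    beta = np.zeros(design.K)
    for name, val in values.items():
        for i, nm in enumerate(design.names):
            if nm == name or nm.startswith(name):
                beta[i] = val
    return beta


class TestInpIO:
    def test_round_trip_identity(self, tmp_path):
        sched = cmr.SurveySchedule(n_primary=4, n_secondary=2)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=6, seed=0))
        path = tmp_path / "h.inp"
        cmr.write_inp(data, path)
        back = cmr.read_inp(path, sched, ["cov"])
        assert np.array_equal(back.histories, data.histories)
        assert np.array_equal(back.freq, data.freq)
        assert np.allclose(back.covariates["cov"], data.covariates["cov"],
                           atol=1e-6)

    def test_single_record_and_comments(self, tmp_path):
        sched = cmr.SurveySchedule(n_primary=2, n_secondary=2)
        path = tmp_path / "h.inp"
        path.write_text("/* header */\n1100 1;\n/* trailing */\n")
        data = cmr.read_inp(path, sched)
        assert data.n_individuals == 1
        assert data.first_event[0] == 0

    @pytest.mark.parametrize("bad,msg", [
        ("110 1;", "length"),
        ("11x0 1;", "non-binary"),
        ("1100 0;", "zero frequency"),
    ])
    def test_parse_errors_carry_line_number(self, tmp_path, bad, msg):
        sched = cmr.SurveySchedule(n_primary=2, n_secondary=2)
        path = tmp_path / "h.inp"
        path.write_text("1100 2;\n" + bad + "\n")
        with pytest.raises(ValueError, match=f"line 2.*{msg}"):
            cmr.read_inp(path, sched)


class TestLikelihood:
    def test_single_interval_closed_form(self):
        # one release, one later primary with one event, no emigration:
        # P(detected) = S·p, P(not) = 1 − S·p
        sched = cmr.SurveySchedule(n_primary=2, n_secondary=1)
        spec = simple_spec()
        s, p = 0.85, 0.6
        probs = {}
        for tail in (0, 1):
            data = make_data([[1, tail]], sched)
            d = _ModelDesign(data, spec)
            beta = beta_for(d, **{"S:int": logit(s), "gpp:int": -40.0,
                                  "gp:int": -40.0, "p:int": logit(p),
                                  "c:int": 0.0})
            probs[tail] = np.exp(-d.negloglik(beta))
        assert probs[1] == pytest.approx(s * p, abs=1e-10)
        assert probs[0] == pytest.approx(1 - s * p, abs=1e-10)
        assert probs[0] + probs[1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_sums_to_one(self, seed):
        # all 2^6 post-release histories over 3 primaries × 2 events
        sched = cmr.SurveySchedule(n_primary=4, n_secondary=2)
        spec = cmr.SurvivalModelSpec()
        rng = np.random.default_rng(seed)
        beta = None
        total = 0.0
        for tail in itertools.product([0, 1], repeat=6):
            hist = [0, 1] + list(tail)  # release at the last event of primary 0
            d = _ModelDesign(make_data([hist], sched), spec)
            if beta is None:
                beta = rng.normal(0.0, 0.8, d.K)
            total += np.exp(-d.negloglik(beta))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_with_within_primary_recaptures(self):
        # release mid-history: condition on first capture at event 0 of
        # primary 0 and enumerate the remaining 7 events
        sched = cmr.SurveySchedule(n_primary=4, n_secondary=2)
        spec = cmr.SurvivalModelSpec()
        rng = np.random.default_rng(11)
        beta = None
        total = 0.0
        for tail in itertools.product([0, 1], repeat=7):
            hist = [1] + list(tail)
            d = _ModelDesign(make_data([hist], sched), spec)
            if beta is None:
                beta = rng.normal(0.0, 0.6, d.K)
            total += np.exp(-d.negloglik(beta))
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_to_cjs_without_emigration(self, seed):
        # gamma' = gamma'' = 0 and one secondary event per primary:
        # the likelihood equals the closed-form CJS expression
        T = 6
        sched = cmr.SurveySchedule(n_primary=T, n_secondary=1)
        spec = cmr.SurvivalModelSpec(gamma_age=False)
        rng = np.random.default_rng(seed)
        s_int = rng.normal(1.0, 0.5)
        s_age = rng.normal(0.0, 0.3)
        p_logits = rng.normal(0.3, 0.7, T)
        f = rng.integers(0, T - 1)
        hist = np.zeros(T, dtype=np.uint8)
        hist[f] = 1
        hist[f + 1:] = rng.random(T - f - 1) < 0.5
        data = make_data([hist], sched)
        d = _ModelDesign(data, spec)
        beta = np.zeros(d.K)
        beta[d.names.index("S:int")] = s_int
        beta[d.names.index("S:age")] = s_age
        beta[d.names.index("gpp:int")] = -40.0
        beta[d.names.index("gp:int")] = -40.0
        for t in range(T):
            beta[d.names.index(f"p:t{t}")] = p_logits[t]
        nll = d.negloglik(beta)

        # independent CJS oracle
        phi = expit(s_int + s_age * (np.arange(T - 1) - f))
        p = expit(p_logits)
        chi = np.ones(T)
        for t in range(T - 2, -1, -1):
            chi[t] = 1 - phi[t] * (1 - (1 - p[t + 1]) * chi[t + 1])
        detections = np.nonzero(hist)[0]
        last = detections[-1]
        lik = 1.0
        for t in range(f, last):
            lik *= phi[t] * (p[t + 1] if hist[t + 1] else 1 - p[t + 1])
        lik *= chi[last]
        assert nll == pytest.approx(-np.log(lik), abs=1e-8)

    def test_likelihood_vs_simulation_frequencies(self):
        # empirical history frequencies from the generator match the model
        sched = cmr.SurveySchedule(n_primary=3, n_secondary=2)
        design = sp.CMRSimDesign(schedule=sched, n_released_per_occasion=4000,
                                 s_intercept=logit(0.8), gamma_prime=0.2,
                                 gamma_dprime=0.15, p_per_occasion=0.65,
                                 c_per_occasion=0.5, seed=123)
        data = sp.gen_encounter_histories(design)
        cohort0 = data.histories[data.first_primary == 0]
        spec = simple_spec()
        counts = {}
        for h in map(tuple, cohort0):
            counts[h] = counts.get(h, 0) + 1
        n0 = len(cohort0)
        for hist, cnt in counts.items():
            d = _ModelDesign(make_data([list(hist)], sched), spec)
            beta = beta_for(d, **{
                "S:int": logit(0.8), "gpp:int": logit(0.15),
                "gp:int": logit(0.2), "p:int": logit(0.65),
                "c:int": logit(0.5)})
            prob = np.exp(-d.negloglik(beta))
            se = np.sqrt(prob * (1 - prob) / n0)
            assert abs(cnt / n0 - prob) < 4 * se + 0.005


class TestFitting:
    def test_intercept_recovery(self):
        sched = cmr.SurveySchedule.from_date_range("2012-01", "2016-02")
        truth = expit(1.7)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=167, seed=7))
        fit = cmr.fit_model(data, cmr.SurvivalModelSpec(), n_restarts=0,
                            seed=1)
        est = cmr.real_survival(fit, 0)
        assert abs(est.estimate - truth) <= 0.03
        assert est.ci_lo < truth < est.ci_hi

    def test_age_dependent_survival_recovery(self):
        # first-season survival recovered within 0.03 (median over seeds)
        sched = cmr.SurveySchedule.from_date_range("2012-01", "2016-02")
        errors = []
        for seed in (1, 2, 3):
            data = sp.gen_encounter_histories(sp.CMRSimDesign(
                schedule=sched, n_released_per_occasion=167,
                s_intercept=1.4, s_age_slope=0.15, seed=seed))
            fit = cmr.fit_model(data, cmr.SurvivalModelSpec(), n_restarts=0,
                                seed=seed, compute_hessian=False)
            est = cmr.real_survival(fit, 0)
            errors.append(abs(est.estimate - expit(1.4)))
        assert np.median(errors) <= 0.03

    def test_nested_deviance_monotone(self):
        sched = cmr.SurveySchedule(n_primary=6, n_secondary=2)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=60, seed=4))
        null = cmr.fit_model(data, simple_spec(), n_restarts=1, seed=0,
                             compute_hessian=False)
        alt = cmr.fit_model(data, simple_spec(s_age=True), n_restarts=1,
                            seed=0, compute_hessian=False)
        assert alt.loglik >= null.loglik - 1e-6
        stat, df, p = cmr.lrt(null, alt)
        assert stat >= 0 and df == 1 and 0 <= p <= 1


class TestWeightsAndAveraging:
    def _dummy(self, aicc_value, key="k"):
        return cmr.ModelFit(spec=cmr.SurvivalModelSpec(name="m"),
                            beta=np.zeros(1), cov_matrix=np.zeros((1, 1)),
                            loglik=0.0, K=1, ess=10, aicc=aicc_value,
                            param_names=["S:int"], converged=True,
                            gradient_norm=0.0, data_key=key)

    def test_equal_aicc_splits_half(self):
        w = cmr.akaike_weights([self._dummy(100.0), self._dummy(100.0)])
        assert np.allclose(w, [0.5, 0.5])

    def test_delta_two_closed_form(self):
        w = cmr.akaike_weights([self._dummy(100.0), self._dummy(102.0)])
        expected = np.array([1.0, np.exp(-1.0)])
        assert np.allclose(w, expected / expected.sum(), atol=1e-6)
        assert w.sum() == pytest.approx(1.0)

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError, match="different datasets"):
            cmr.akaike_weights([self._dummy(1.0, "a"), self._dummy(2.0, "b")])

    def test_model_average_formula(self):
        theta, var = cmr.model_average([0.8, 0.9], [0.0, 0.0], [0.5, 0.5])
        assert theta == pytest.approx(0.85)
        assert var == pytest.approx(0.0025)

    def test_model_average_is_convex(self):
        rng = np.random.default_rng(0)
        est = rng.uniform(0.2, 0.9, 6)
        w = rng.dirichlet(np.ones(6))
        theta, _ = cmr.model_average(est, np.zeros(6), w)
        assert est.min() <= theta <= est.max()

    def test_single_model_identity(self):
        theta, var = cmr.model_average([0.7], [0.01], [1.0])
        assert theta == 0.7 and var == pytest.approx(0.01)


class TestGroupAndCovariateEffects:
    def test_group_gap_detected_by_aicc(self):
        # first-season survival gaps of ~0.045 and ~0.07 among 3 groups
        sched = cmr.SurveySchedule.from_date_range("2012-01", "2016-02")
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            data = sp.gen_encounter_histories(sp.CMRSimDesign(
                schedule=sched, n_released_per_occasion=167,
                s_intercept=logit(0.85), group_offsets=(-0.43, 0.43),
                seed=100 + seed))
            null = cmr.fit_model(data, cmr.SurvivalModelSpec(), n_restarts=0,
                                 seed=0, compute_hessian=False)
            grp = cmr.fit_model(
                data, cmr.SurvivalModelSpec(name="S(A+group)",
                                            group_effect="additive"),
                n_restarts=0, seed=0, compute_hessian=False)
            if grp.aicc < null.aicc:
                wins += 1
        assert wins >= int(0.8 * n_seeds)

    def test_covariate_effect_recovery(self):
        # beta = −0.5 on first-season survival: recovered, CI excludes zero
        sched = cmr.SurveySchedule.from_date_range("2012-01", "2016-02")
        errs, significant = [], 0
        n_seeds = 5
        for seed in range(n_seeds):
            data = sp.gen_encounter_histories(sp.CMRSimDesign(
                schedule=sched, n_released_per_occasion=250,
                cov_beta=-0.5, seed=200 + seed))
            fit = cmr.covariate_effect_models(data, "cov", "linear",
                                              "first_season", n_restarts=0,
                                              seed=0)
            est, lo, hi, sig = fit.beta_ci("S:cov")
            errs.append(abs(est - (-0.5)))
            significant += int(sig and est < 0)
        assert np.median(errs) <= 0.15
        assert significant >= int(0.8 * n_seeds)

    def test_null_covariate_ci_coverage(self):
        sched = cmr.SurveySchedule.from_date_range("2012-01", "2016-02")
        covered = 0
        n_seeds = 5
        for seed in range(n_seeds):
            data = sp.gen_encounter_histories(sp.CMRSimDesign(
                schedule=sched, n_released_per_occasion=125,
                cov_beta=0.0, seed=300 + seed))
            fit = cmr.covariate_effect_models(data, "cov", "linear",
                                              "first_season", n_restarts=0,
                                              seed=0)
            _, lo, hi, sig = fit.beta_ci("S:cov")
            covered += int(lo <= 0.0 <= hi)
        assert covered >= 4

    def test_quadratic_adds_one_parameter(self):
        sched = cmr.SurveySchedule(n_primary=4, n_secondary=2)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=20, seed=0))
        d_lin = _ModelDesign(data, cmr.SurvivalModelSpec(
            covariate="cov", cov_form="linear"))
        d_quad = _ModelDesign(data, cmr.SurvivalModelSpec(
            covariate="cov", cov_form="quadratic"))
        assert d_quad.K == d_lin.K + 1

    def test_constant_covariate_rejected(self):
        sched = cmr.SurveySchedule(n_primary=3, n_secondary=2)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=10, seed=0))
        data.covariates["cov"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cmr.covariate_effect_models(data, "cov")


class TestLRT:
    def test_identical_models(self):
        sched = cmr.SurveySchedule(n_primary=4, n_secondary=2)
        data = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=30, seed=1))
        fit = cmr.fit_model(data, simple_spec(), n_restarts=0, seed=0,
                            compute_hessian=False)
        stat, df, p = cmr.lrt(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_null_calibration(self):
        # LRT p-values approximately uniform when the extra term is absent
        sched = cmr.SurveySchedule(n_primary=6, n_secondary=2)
        pvals = []
        for seed in range(100):
            data = sp.gen_encounter_histories(sp.CMRSimDesign(
                schedule=sched, n_released_per_occasion=30,
                gamma_prime=0.05, gamma_dprime=0.05, seed=seed))
            null = cmr.fit_model(data, simple_spec(), n_restarts=0, seed=0,
                                 compute_hessian=False)
            alt = cmr.fit_model(data, simple_spec(s_age=True), n_restarts=0,
                                seed=0, compute_hessian=False)
            pvals.append(cmr.lrt(null, alt)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestModelSet:
    def test_five_model_phenotype_set_runs_and_ranks(self):
        sched = cmr.SurveySchedule(n_primary=5, n_secondary=2)
        base = sp.gen_encounter_histories(sp.CMRSimDesign(
            schedule=sched, n_released_per_occasion=60,
            group_offsets=(-0.4, 0.0, 0.4), seed=5))
        groups4 = base.groups
        groups3 = np.minimum(groups4, 2)  # lump two groups
        data3 = base.with_groups(groups3)
        data4 = base.with_groups(groups4)
        fits = cmr.phenotype_group_model_set(data3, data4, n_restarts=0,
                                             seed=0, compute_hessian=False)
        assert len(fits) == 5
        table = cmr.model_selection_table(fits)
        assert table["W"].sum() == pytest.approx(1.0)
        assert table["dAICc"].iloc[0] == 0.0
        # model-averaged first-season survival is a valid probability
        est = cmr.model_average_survival(fits, age=0, group=0)
        assert 0.0 <= est.ci_lo <= est.estimate <= est.ci_hi <= 1.0


class TestFormulaStrings:
    def test_full_model_round_trip(self):
        spec = cmr.SurvivalModelSpec.from_string("S(A) gpp(A) gp(A) p(t) c(t)")
        assert spec == cmr.SurvivalModelSpec(name="S(A) gpp(A) gp(A) p(t) c(t)")

    def test_group_and_covariate_terms(self):
        spec = cmr.SurvivalModelSpec.from_string(
            "S(A+group) gpp(A) gp(A) p(t) c(t)")
        assert spec.group_effect == "additive" and spec.s_age
        spec = cmr.SurvivalModelSpec.from_string(
            "S(Axgroup) gpp(A) gp(A) p(t) c(t)")
        assert spec.group_effect == "multiplicative"
        spec = cmr.SurvivalModelSpec.from_string(
            "S(A+aspect_ratio^2@first_year) gpp(A) gp(A) p(t) c(t)")
        assert spec.covariate == "aspect_ratio"
        assert spec.cov_form == "quadratic"
        assert spec.cov_window_ages == cmr.COVARIATE_WINDOWS["first_year"]

    def test_constant_terms_and_errors(self):
        spec = cmr.SurvivalModelSpec.from_string("S(.) gpp(.) gp(.) p(.) c(.)")
        assert not (spec.s_age or spec.gamma_age or spec.p_time or spec.c_time)
        with pytest.raises(ValueError, match="no S"):
            cmr.SurvivalModelSpec.from_string("p(t) c(t)")
        with pytest.raises(ValueError, match="window"):
            cmr.SurvivalModelSpec.from_string("S(A+x@next_year) p(t)")
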