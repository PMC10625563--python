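import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

import pairmnar as pm
from pairmnar.stage1 import (
    Stage1Sample,
    _wald_statistic,
    estimate_W,
    extract_stage1_sample,
    mle_fit,
    pseudo_likelihood_fit,
)


def make_sample(y, X, r=None, columns=None):
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    r = np.ones(len(y), dtype=bool) if r is None else np.asarray(r, dtype=bool)
    columns = columns or tuple(f"x{k}" for k in range(X.shape[1]))
    return Stage1Sample(
        y=y, X=X, r=r, columns=tuple(columns),
        subject_ids=tuple(str(i) for i in range(len(y))),
    )


# ---------------------------------------------------------------------------
# cross-sectional extraction
# ---------------------------------------------------------------------------

class TestExtractStage1Sample:
    @pytest.fixture
    def spec(self):
        return pm.ModelSpec(covariate_names=("age", "sex"), center_list=())

    def test_subject_mean_arithmetic(self, toy_subjects, spec):
        series = pd.DataFrame(
            {
                "subject_id": ["A", "A"], "day": [0, 1],
                "observed": True, "weight": [197.0, 195.0],
            }
        )
        ds = pm.LongitudinalDataset(toy_subjects, series, schedule_length=3)
        sample = extract_stage1_sample(ds, spec, summary="subject_mean")
        a = sample.subject_ids.index("A")
        assert sample.y[a] == pytest.approx(-4.0)  # mean of -3 and -5
        assert sample.r[a]

    def test_silent_subject_is_incomplete(self, toy_subjects, spec):
        series = pd.DataFrame(
            {
                "subject_id": ["A"], "day": [0],
                "observed": True, "weight": [197.0],
            }
        )
        ds = pm.LongitudinalDataset(toy_subjects, series, schedule_length=3)
        sample = extract_stage1_sample(ds, spec, summary="subject_mean")
        b = sample.subject_ids.index("B")
        assert not sample.r[b]
        assert np.isnan(sample.y[b])

    def test_milestone_day_half_open_boundary(self, toy_dataset, spec):
        with pytest.raises(ValueError, match="milestone"):
            extract_stage1_sample(
                toy_dataset, spec, summary="milestone_day", milestone_day=3
            )

    def test_milestone_day_uses_that_day_only(self, toy_dataset, spec):
        sample = extract_stage1_sample(
            toy_dataset, spec, summary="milestone_day", milestone_day=1
        )
        a = sample.subject_ids.index("A")
        b = sample.subject_ids.index("B")
        assert sample.r[a] and not sample.r[b]  # B missed day 1
        assert sample.y[a] == pytest.approx(198.5 - 200.0)

    def test_time_varying_covariates_rejected(self, toy_dataset):
        spec = pm.ModelSpec(covariate_names=("age", "time"), center_list=())
        with pytest.raises(ValueError, match="subject-level"):
            extract_stage1_sample(toy_dataset, spec)


# ---------------------------------------------------------------------------
# complete-case maximum likelihood
# ---------------------------------------------------------------------------

class TestMleFit:
    def test_two_point_interpolation_known_dispersion(self):
        sample = make_sample([0.0, 1.0], [[0.0], [1.0]])
        fit = mle_fit(sample, pm.ExpFamSpec(dispersion=1.0))
        assert np.allclose(fit.beta_nat, [0.0, 1.0], atol=1e-12)

    def test_constant_outcome_known_dispersion(self):
        sample = make_sample([3.0, 3.0, 3.0], [[0.0], [1.0], [2.0]])
        fit = mle_fit(sample, pm.ExpFamSpec(dispersion=2.0))
        assert fit.beta_nat[1] == pytest.approx(0.0, abs=1e-12)
        assert fit.beta_nat[0] == pytest.approx(3.0 / 2.0)

    def test_constant_outcome_estimated_dispersion_unidentified(self):
        sample = make_sample([3.0, 3.0, 3.0], [[0.0], [1.0], [2.0]])
        with pytest.raises(pm.UnidentifiedModelError, match="dispersion"):
            mle_fit(sample, pm.ExpFamSpec())

    def test_matches_numeric_likelihood_maximizer(self):
        # oracle: maximize the exponential-dispersion log-likelihood
        # numerically over (alpha, slope, log dispersion)
        rng = np.random.default_rng(10)
        x = rng.normal(size=5)
        y = 0.4 + 0.8 * x + rng.normal(size=5)
        sample = make_sample(y, x[:, None])

        def negll(theta):
            a, b, loglam = theta
            lam = np.exp(loglam)
            eta = a + b * x
            return -np.sum(
                (y * eta - eta**2 / 2.0) / lam
                - y**2 / (2.0 * lam)
                - 0.5 * np.log(2.0 * np.pi * lam)
            )

        opt = optimize.minimize(
            negll, x0=[0.0, 0.0, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        a, b, lam = opt.x[0], opt.x[1], np.exp(opt.x[2])
        fit = mle_fit(sample, pm.ExpFamSpec())
        assert np.allclose(fit.beta_nat, [a / lam, b / lam], atol=1e-6)

    def test_rank_deficient_design(self):
        sample = make_sample(
            [0.0, 1.0, 2.0, 3.0],
            np.column_stack([[1, 1, 1, 1.0], [2, 2, 2, 2.0]]),
        )
        with pytest.raises(pm.UnidentifiedModelError):
            mle_fit(sample, pm.ExpFamSpec())

    def test_too_few_complete_records(self):
        sample = make_sample([0.0, 1.0], [[0.0], [1.0]])
        with pytest.raises(pm.InsufficientDataError):
            mle_fit(sample, pm.ExpFamSpec())  # estimated dispersion needs m+2

    def test_bernoulli_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        p = 1.0 / (1.0 + np.exp(-(0.3 - 0.9 * x)))
        y = (rng.random(200) < p).astype(float)
        sample = make_sample(y, x[:, None])
        fit = mle_fit(sample, pm.ExpFamSpec(family="bernoulli_logit"))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.beta_nat, ref.params, atol=1e-6)


# ---------------------------------------------------------------------------
# semiparametric pseudo-likelihood
# ---------------------------------------------------------------------------

class TestPseudoLikelihoodFit:
    def test_constant_outcome_unidentified(self):
        sample = make_sample([2.0, 2.0, 2.0, 2.0], [[0], [1], [2], [3.0]])
        with pytest.raises(pm.UnidentifiedModelError, match="flat|constant"):
            pseudo_likelihood_fit(sample, pm.ExpFamSpec())

    def test_slope_matches_dense_grid_search(self):
        # oracle: refine a dense grid over the 1-d pairwise objective
        y = np.array([0.3, -1.2, 0.8, 2.1])
        x = np.array([0.0, 1.0, -0.5, 1.5])
        sample = make_sample(y, x[:, None])

        def objective(b):
            tot = 0.0
            for i in range(4):
                for j in range(i + 1, 4):
                    u = b * (x[i] - x[j]) * (y[i] - y[j])
                    tot += -np.logaddexp(0.0, -u)
            return tot

        lo, hi = -5.0, 5.0
        for _ in range(6):
            grid = np.linspace(lo, hi, 2001)
            vals = [objective(b) for b in grid]
            k = int(np.argmax(vals))
            lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 2000)]
        b_star = (lo + hi) / 2.0

        fit = pseudo_likelihood_fit(sample, pm.ExpFamSpec(dispersion=1.0))
        assert fit.beta_nat[1] == pytest.approx(b_star, abs=1e-4)

    def test_agrees_with_mle_under_mcar_at_large_n(self):
        # both estimators are consistent for the same natural-parameter
        # vector when data are (completely) at random
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        y = 0.5 + 0.7 * x + rng.normal(size=n)
        r = rng.random(n) < 0.8
        sample = make_sample(y, x[:, None], r=r)
        hat = mle_fit(sample, pm.ExpFamSpec())
        til = pseudo_likelihood_fit(sample, pm.ExpFamSpec())
        # 3 Monte-Carlo standard errors on each natural-scale component
        se = np.sqrt(np.diag(estimate_W(sample, hat, til)) / sample.n_complete)
        assert np.all(np.abs(til.beta_nat - hat.beta_nat) <= 3 * se)

    def test_profile_mean_intercept_matches_closed_form(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = 1.0 - 0.4 * x + rng.normal(size=50)
        sample = make_sample(y, x[:, None])
        fit = pseudo_likelihood_fit(
            sample, pm.ExpFamSpec(), intercept_method="profile_mean"
        )
        lam = fit.lam
        slope_mean = lam * fit.beta_nat[1]
        alpha_mean = y.mean() - slope_mean * x.mean()
        assert fit.beta_nat[0] == pytest.approx(alpha_mean / lam, rel=1e-10)

    def test_bernoulli_profiled_intercept_solves_score(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        p = 1.0 / (1.0 + np.exp(-(0.2 + 0.8 * x)))
        y = (rng.random(300) < p).astype(float)
        sample = make_sample(y, x[:, None])
        fit = pseudo_likelihood_fit(sample, pm.ExpFamSpec(family="bernoulli_logit"))
        alpha, slope = fit.beta_nat[0], fit.beta_nat[1:]
        resid = y - 1.0 / (1.0 + np.exp(-(alpha + x * slope[0])))
        assert abs(resid.sum()) < 1e-8


# ---------------------------------------------------------------------------
# weighting matrix and test statistic
# ---------------------------------------------------------------------------

class TestWeightingMatrix:
    def _fit_pair(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.3 + 0.5 * x + rng.normal(size=n)
        sample = make_sample(y, x[:, None])
        return sample, mle_fit(sample, pm.ExpFamSpec()), \
            pseudo_likelihood_fit(sample, pm.ExpFamSpec())

    def test_identical_influences_give_zero_matrix(self):
        sample, hat, til = self._fit_pair()
        W = estimate_W(sample, hat, hat)
        assert np.allclose(W, 0.0, atol=1e-15)

    def test_symmetric_psd(self):
        sample, hat, til = self._fit_pair(seed=2)
        W = estimate_W(sample, hat, til)
        assert np.allclose(W, W.T)
        assert np.linalg.eigvalsh(W).min() >= -1e-10

    def test_hand_summed_outer_products(self):
        # 3 records with made-up influence values: direct summation oracle
        from pairmnar.stage1 import _Fit

        phi_hat = np.array([[1.0, 0.5], [-0.2, 0.1], [0.4, -0.3]])
        phi_til = np.array([[0.8, 0.7], [0.1, -0.2], [0.2, 0.0]])
        d = phi_til - phi_hat
        expected = sum(np.outer(di, di) for di in d) / 3.0
        W = estimate_W(
            None,
            _Fit(beta_nat=np.zeros(2), influence=phi_hat, lam=1.0),
            _Fit(beta_nat=np.zeros(2), influence=phi_til, lam=1.0),
        )
        assert np.allclose(W, expected, atol=1e-12)


class TestWaldStatistic:
    def test_zero_contrast_gives_zero_statistic(self):
        W = np.diag([1.0, 2.0, 3.0])
        T, df, p = _wald_statistic(np.zeros(3), W, 100)
        assert T == 0.0 and df == 3 and p == 1.0

    def test_chi2_tail_against_numerical_integration(self):
        # T = 9.12 on 3 degrees of freedom
        T = 9.12
        p = float(stats.chi2.sf(T, 3))
        dens = lambda t: stats.chi2.pdf(t, 3)
        p_num, _ = integrate.quad(dens, T, np.inf)
        assert p == pytest.approx(p_num, abs=1e-8)
        assert p == pytest.approx(0.0277, abs=5e-4)

    def test_rank_deficient_W_reduces_df(self):
        v = np.array([1.0, 2.0, 0.0])
        W = np.outer(v, v)  # rank one
        delta = 0.05 * v
        T, df, p = _wald_statistic(delta, W, 50)
        assert df == 1
        # delta' W+ delta = 0.05^2 * v'(vv')+ v = 0.05^2
        assert T == pytest.approx(50 * 0.05**2, rel=1e-10)

    def test_zero_matrix_is_degenerate(self):
        with pytest.raises(pm.DegenerateTestError):
            _wald_statistic(np.ones(2), np.zeros((2, 2)), 10)


class TestMnarTest:
    def _simulate(self, mech, n=300, seed=1, beta=(0.03, -0.5)):
        spec = pm.ModelSpec(covariate_names=("age", "sex"), center_list=("age",))
        cfg = pm.SimulationConfig(
            n_subjects=n, schedule_length=1, model=spec,
            true_beta=beta, seed=seed,
        )
        ds = pm.simulate_complete_cohort(cfg)
        return pm.apply_missingness(ds, mech, seed + 1), spec

    def test_two_covariates_give_df_3(self):
        data, spec = self._simulate(
            pm.MissingnessMechanism(kind="MCAR", p_const=0.7)
        )
        res = pm.mnar_test(data, spec)
        assert res.df == 3
        assert res.T >= 0.0
        assert 0.0 <= res.p_value <= 1.0
        assert res.columns == ("intercept", "age", "sex")

    def test_plugin_and_jackknife_agree_in_order_of_magnitude(self):
        data, spec = self._simulate(
            pm.MissingnessMechanism(kind="MCAR", p_const=0.8), seed=4
        )
        a = pm.mnar_test(data, spec, w_method="plugin")
        b = pm.mnar_test(data, spec, w_method="jackknife")
        assert a.df == b.df == 3
        assert np.allclose(a.beta_tilde, b.beta_tilde)
        assert 0.2 < a.T / b.T < 5.0

    def test_affine_covariate_rescaling_leaves_T_invariant(self):
        mech = pm.MissingnessMechanism(kind="MCAR", p_const=0.75)
        data, spec = self._simulate(mech, seed=7)
        res = pm.mnar_test(data, spec)
        # rescale age to decades and flip the sex coding (affine maps)
        subjects2 = [
            pm.Subject(s.subject_id, s.arm, s.age / 10.0, 1 - s.sex,
                       s.baseline_bmi, s.baseline_weight)
            for s in data.subjects
        ]
        data2 = pm.LongitudinalDataset(
            subjects=subjects2, series=data.series.copy(),
            schedule_length=data.schedule_length,
        )
        res2 = pm.mnar_test(data2, spec)
        assert res2.T == pytest.approx(res.T, rel=1e-6)
        assert res2.df == res.df

    def test_milestone_summary_runs(self):
        data, spec = self._simulate(
            pm.MissingnessMechanism(kind="MCAR", p_const=0.9), seed=9
        )
        res = pm.mnar_test(data, spec, summary="milestone_day", milestone_day=0)
        assert res.df == 3
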