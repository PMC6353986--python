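"""Variance components: Gaussian ML/REML, NPML EM, model comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

import sitepool as sp
from sitepool.varcomp import (
    _EMState,
    _em_loglik_resp,
    _run_em,
    build_design,
    fit_gaussian_lmm,
    fit_npml,
)

from conftest import anova_variance_components, two_site_toy

pytestmark = pytest.mark.filterwarnings("ignore:only .* sites")


def _flat_cohort(y, sites):
    """Cohort with constant age/sex so the design is intercept-only."""
    return pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(len(y))],
            "site_id": sites,
            "sex": ["girl"] * len(y),
            "age_months": [24.0] * len(y),
            "score": y,
        }
    )


class TestGaussianLMM:
    def test_balanced_toy_matches_anova_reml(self):
        """A={0,2}, B={4,6}: REML equals the one-way ANOVA closed form
        (s2w=2, s2b=(MSB-MSW)/n=7, pct=77.78)."""
        fit = fit_gaussian_lmm(two_site_toy(), "score", "age_sex", "reml")
        assert fit.sigma2_within == pytest.approx(2.0, abs=1e-6)
        assert fit.sigma2_between == pytest.approx(7.0, abs=1e-6)
        assert fit.pct_between == pytest.approx(100 * 7 / 9, abs=1e-4)

    def test_random_balanced_designs_match_anova(self):
        """REML == ANOVA method-of-moments on balanced designs, tol 1e-6."""
        rng = np.random.default_rng(314)
        for _ in range(10):
            a, n = rng.integers(3, 8), rng.integers(5, 20)
            u = rng.normal(0, rng.uniform(0.1, 2.0), a)
            y = np.repeat(u, n) + rng.normal(0, 1.0, a * n)
            sites = np.repeat([f"s{i}" for i in range(a)], n)
            fit = fit_gaussian_lmm(_flat_cohort(y, sites), "score", "age_sex", "reml")
            s2b_o, s2w_o = anova_variance_components(y, sites)
            assert fit.sigma2_between == pytest.approx(s2b_o, abs=1e-6)
            assert fit.sigma2_within == pytest.approx(s2w_o, abs=1e-6)

    def test_identical_site_means_boundary(self):
        y = [1.0, 3.0, 1.0, 3.0, 1.0, 3.0]
        sites = ["A", "A", "B", "B", "C", "C"]
        fit = fit_gaussian_lmm(_flat_cohort(y, sites), "score", "age_sex", "reml")
        assert fit.sigma2_between == 0.0
        assert fit.pct_between == 0.0

    def test_ml_loglik_equals_direct_density(self):
        """The reported ML log-likelihood is the multivariate normal density
        at the estimates (independent direct computation)."""
        from scipy.stats import multivariate_normal

        fit = fit_gaussian_lmm(two_site_toy(), "score", "age_sex", "ml")
        y = np.array([0.0, 2.0, 4.0, 6.0])
        V = fit.sigma2_within * np.eye(4)
        V[:2, :2] += fit.sigma2_between
        V[2:, 2:] += fit.sigma2_between
        mu = np.full(4, fit.fixed_effects["intercept"])
        assert fit.loglik == pytest.approx(multivariate_normal.logpdf(y, mu, V), abs=1e-8)

    def test_cross_check_statsmodels_with_covariates(self, study_cohort):
        """Independent route: statsmodels MixedLM agrees on the variance
        components and the ML log-likelihood."""
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        y, X, _, codes, _ = build_design(study_cohort, "visual_acuity", "age_sex_fetalhc")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = statsmodels.MixedLM(y, X, groups=codes).fit(reml=False)
        fit = fit_gaussian_lmm(study_cohort, "visual_acuity", "age_sex_fetalhc", "ml")
        assert fit.sigma2_within == pytest.approx(res.scale, rel=1e-4)
        assert fit.sigma2_between == pytest.approx(
            float(np.asarray(res.cov_re).ravel()[0]), rel=1e-3, abs=1e-4
        )
        assert fit.loglik == pytest.approx(res.llf, abs=1e-3)
        assert fit.loglik >= res.llf - 1e-6  # ours is the exact profile max

    def test_recovery_fixed_effects(self):
        """Mean over replicates recovers the 8% ground truth and the age
        slope; a single 5-site replicate is too noisy to pin down."""
        pcts, slopes = [], []
        for seed in range(10):
            cfg = sp.default_study_config(
                seed=99 + seed, site_sizes=(261,) * 5, fix_site_effects=True
            )
            t = sp.generate_cohort(cfg)
            fit = fit_gaussian_lmm(t, "visual_acuity", "age_sex", "reml")
            pcts.append(fit.pct_between)
            slopes.append(fit.fixed_effects["age_c"])
        assert np.mean(pcts) == pytest.approx(8.0, abs=2.0)
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.1)

    def test_reml_flagged_not_comparable(self):
        fit = fit_gaussian_lmm(two_site_toy(), "score", "age_sex", "reml")
        assert not fit.criteria_comparable
        assert fit_gaussian_lmm(two_site_toy(), "score", "age_sex", "ml").criteria_comparable

    def test_single_site_design_error(self):
        t = _flat_cohort([1.0, 2.0, 3.0], ["A", "A", "A"])
        with pytest.raises(sp.DesignError):
            fit_gaussian_lmm(t, "score", "age_sex", "reml")

    def test_bad_method(self):
        with pytest.raises(sp.ConfigurationError):
            fit_gaussian_lmm(two_site_toy(), "score", "age_sex", "mle")


class TestNPML:
    def test_k1_equals_ols(self, small_cohort):
        """K=1 collapses to the fixed-effects-only Gaussian model."""
        vd, mp = fit_npml(small_cohort, "score_a", "age_sex", K=1)
        y, X, _, codes, _ = build_design(small_cohort, "score_a", "age_sex")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        N = len(y)
        ll_ols = -0.5 * (N * np.log(2 * np.pi * rss / N) + N)
        assert vd.sigma2_between == 0.0
        assert vd.loglik == pytest.approx(ll_ols, abs=1e-8)
        assert mp.K == 1

    def test_em_monotone_loglik(self):
        """Log-likelihood trace is non-decreasing at every EM iteration."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = int(rng.integers(3, 8))
            n = int(rng.integers(4, 15))
            y = np.repeat(rng.normal(0, 1, a), n) + rng.normal(0, 1, a * n)
            sites = np.repeat([f"s{i}" for i in range(a)], n)
            t = _flat_cohort(y, sites)
            yv, X, _, codes, _ = build_design(t, "score", "age_sex")
            m = int(codes.max()) + 1
            ni = np.bincount(codes, minlength=m).astype(float)
            ti = np.bincount(codes, weights=yv, minlength=m)
            sxi = np.zeros((m, 0))
            K = int(rng.integers(1, a + 1))
            state0 = _EMState(
                beta=np.zeros(0),
                theta=np.sort(rng.normal(0, 1, K)),
                pi=np.full(K, 1.0 / K),
                s2=1.0,
            )
            _, trace, _ = _run_em(
                yv, X[:, :0], codes, state0, ni, ti, sxi, 1e-8, 1e-6, 2000
            )
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-8 * (1 + np.abs(trace[:-1])))

    def test_two_mass_point_recovery_vs_grid_oracle(self):
        """20 sites x 200 children from two mass points at +/-1 (pi = .5/.5),
        small residual variance: EM recovers locations and masses within
        0.05, and does at least as well as a brute-force grid maximiser."""
        rng = np.random.default_rng(88)
        a, n = 20, 200
        u = np.repeat([-1.0, 1.0], a // 2)
        y = np.repeat(u, n) + rng.normal(0, 0.2, a * n)
        sites = np.repeat([f"s{i:02d}" for i in range(a)], n)
        vd, mp = fit_npml(_flat_cohort(y, sites), "score", "age_sex", K=2)

        assert mp.K == 2
        assert mp.locations[0] == pytest.approx(-1.0, abs=0.05)
        assert mp.locations[1] == pytest.approx(1.0, abs=0.05)
        assert mp.masses[0] == pytest.approx(0.5, abs=0.05)

        # independent oracle: direct marginal likelihood on a parameter grid
        ym = y.reshape(a, n)
        S = ym.sum(axis=1)
        SS = (ym**2).sum(axis=1)
        s2 = float(((ym - ym.mean(axis=1, keepdims=True)) ** 2).sum() / (a * (n - 1)))

        def loglik(th1, th2, pi1):
            best = -np.inf
            th = np.array([th1, th2])
            ssr = SS[:, None] - 2 * np.outer(S, th) + n * th[None, :] ** 2
            logf = -0.5 * (n * np.log(2 * np.pi * s2) + ssr / s2)
            logw = np.log([pi1, 1 - pi1])[None, :] + logf
            m = logw.max(axis=1)
            return float((m + np.log(np.exp(logw - m[:, None]).sum(axis=1))).sum())

        grid_t = np.linspace(-1.3, -0.7, 31)
        grid_u = np.linspace(0.7, 1.3, 31)
        grid_p = np.linspace(0.2, 0.8, 25)
        best_ll, best_par = -np.inf, None
        for t1 in grid_t:
            for t2 in grid_u:
                for p1 in grid_p:
                    ll = loglik(t1, t2, p1)
                    if ll > best_ll:
                        best_ll, best_par = ll, (t1, t2, p1)
        assert vd.loglik >= best_ll - 1e-6
        assert mp.locations[0] == pytest.approx(best_par[0], abs=0.03)
        assert mp.locations[1] == pytest.approx(best_par[1], abs=0.03)
        assert mp.masses[0] == pytest.approx(best_par[2], abs=0.03)

    def test_deterministic(self, small_cohort):
        a = fit_npml(small_cohort, "score_a", "age_sex", K=2, start_seed=3)
        b = fit_npml(small_cohort, "score_a", "age_sex", K=2, start_seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1].locations, b[1].locations)

    def test_loglik_nondecreasing_in_k(self, small_cohort):
        lls = [
            fit_npml(small_cohort, "score_a", "age_sex", K=k)[0].loglik
            for k in (1, 2, 3)
        ]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6

    def test_k_auto_selects_by_bic(self, small_cohort):
        vd, mp = fit_npml(small_cohort, "score_a", "age_sex", K="auto")
        assert 1 <= mp.K <= 3
        # selected BIC is minimal among explicit-K fits
        bics = [
            fit_npml(small_cohort, "score_a", "age_sex", K=k)[0].bic for k in (1, 2, 3)
        ]
        assert vd.bic == pytest.approx(min(bics), abs=1e-6)

    def test_k_out_of_range(self, small_cohort):
        with pytest.raises(sp.ConfigurationError):
            fit_npml(small_cohort, "score_a", "age_sex", K=4)

    def test_duplicate_mass_points_merged(self):
        """A one-cluster dataset fitted with K=3 collapses its support."""
        rng = np.random.default_rng(17)
        y = rng.normal(0, 1, 120)
        sites = np.repeat([f"s{i}" for i in range(6)], 20)
        _, mp = fit_npml(_flat_cohort(y, sites), "score", "age_sex", K=3)
        assert mp.K <= 3
        assert np.all(np.diff(mp.locations) > 0)
        assert mp.masses.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mass_point_distribution_invariants(self):
        with pytest.raises(sp.ConfigurationError):
            sp.MassPointDistribution(np.array([0.0, 0.0]), np.array([0.5, 0.5]))
        with pytest.raises(sp.ConfigurationError):
            sp.MassPointDistribution(np.array([0.0, 1.0]), np.array([0.6, 0.6]))


class TestPctBetweenAndComparison:
    @pytest.mark.parametrize(
        "s2b, s2w, expected",
        [(0.0, 5.0, 0.0), (1.0, 9.0, 10.0), (7.0, 2.0, 100 * 7 / 9)],
    )
    def test_pct_between_arithmetic(self, s2b, s2w, expected):
        vd = sp.VarianceDecomposition(
            domain="d", method="gaussian_ml", covariate_set="age_sex",
            sigma2_between=s2b, sigma2_within=s2w, loglik=0.0, aic=0.0, bic=0.0,
            n_children=10, n_sites=2, df_model=3,
        )
        assert sp.pct_between(vd) == pytest.approx(expected, abs=1e-10)

    def _vd(self, **kw):
        base = dict(
            domain="d", method="gaussian_ml", covariate_set="age_sex",
            sigma2_between=1.0, sigma2_within=9.0, loglik=-50.0, aic=100.0,
            bic=105.0, n_children=20, n_sites=4, df_model=3,
        )
        base.update(kw)
        return sp.VarianceDecomposition(**base)

    def test_select_minimal(self):
        cmp = sp.compare_models([self._vd(aic=100.0), self._vd(aic=110.0)], "aic")
        assert cmp.selected.aic == 100.0

    def test_single_fit_trivial(self):
        f = self._vd()
        assert sp.compare_models([f], "bic").selected is f

    def test_mismatched_samples_error(self):
        with pytest.raises(sp.ComparisonError):
            sp.compare_models([self._vd(), self._vd(n_children=19)])

    def test_reml_across_fixed_effect_sets_refused(self):
        a = self._vd(method="gaussian_reml", criteria_comparable=False)
        b = self._vd(
            method="gaussian_reml", covariate_set="age_sex_fetalhc",
            criteria_comparable=False,
        )
        with pytest.raises(sp.ComparisonError, match="REML"):
            sp.compare_models([a, b])

    def test_npml_not_preferred_on_gaussian_data(self):
        """On Gaussian-generated sites, the extra mass-point parameters are
        BIC-penalised: NPML should not systematically beat Gaussian ML."""
        wins = 0
        reps = 12
        for seed in range(reps):
            cfg = sp.GeneratorConfig(
                site_sizes=(80,) * 5,
                domains=(sp.DomainSpec(name="s", pct_between_target=10.0),),
                seed=1000 + seed,
            )
            t = sp.generate_cohort(cfg)
            g = fit_gaussian_lmm(t, "s", "age_sex", "ml")
            npml, _ = fit_npml(t, "s", "age_sex", K="auto")
            if npml.bic < g.bic:
                wins += 1
        assert wins <= reps // 2


def test_variance_table_shape(small_cohort):
    tab = sp.variance_table(
        small_cohort, domains=["score_a"], covariate_sets=("age_sex",), method="reml"
    )
    assert tab.shape == (1, 1)
    assert 0.0 <= tab.iloc[0, 0] < 100.0
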