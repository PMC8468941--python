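import numpy as np
import pytest

from voltraj import synthetic_data as sd
from voltraj.errors import (
    DomainError,
    InsufficientDataError,
    NonIdentifiabilityError,
    PropagationError,
    StateError,
)
from voltraj.normative_model import (
    FitSettings,
    GrowthFit,
    IndividualScan,
    confidence_band,
    default_age_grid,
    evaluate_hybrid,
    fit_hybrid,
    fit_hybrid_xy,
    hybrid_gradient,
    mc_band,
    measure_values,
    prediction_band,
    read_scans,
    write_scans,
)

BETA_EXAMPLE = np.array([100.0, 1.0, -0.1, 0.001, 50.0, 2.0])


# ---------------------------------------------------------------------------
# Mean curve and gradient
# ---------------------------------------------------------------------------

class TestEvaluateHybrid:
    def test_age_zero_returns_intercept(self):
        assert evaluate_hybrid(BETA_EXAMPLE, 0.0) == pytest.approx(100.0)

    def test_saturation_asymptote(self):
        beta = np.array([100.0, 0.0, 0.0, 0.0, 50.0, 2.0])
        assert evaluate_hybrid(beta, 1e4) == pytest.approx(150.0)

    def test_hand_computed_value(self):
        # 100 + 10 - 10 + 1 + 50*(1 - e^-5); e^-5 = 0.00673794699...
        assert evaluate_hybrid(BETA_EXAMPLE, 10.0) == pytest.approx(
            150.6631026500457, rel=1e-12
        )

    def test_vectorized(self):
        ages = np.array([0.0, 10.0])
        values = evaluate_hybrid(BETA_EXAMPLE, ages)
        assert values.shape == (2,)
        assert values[0] == pytest.approx(100.0)

    def test_non_positive_beta5(self):
        bad = BETA_EXAMPLE.copy()
        bad[5] = 0.0
        with pytest.raises(DomainError):
            evaluate_hybrid(bad, 1.0)


class TestHybridGradient:
    def test_age_zero(self):
        assert hybrid_gradient(BETA_EXAMPLE, 0.0) == pytest.approx(
            [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        )

    def test_zero_beta4_kills_beta5_sensitivity(self):
        beta = np.array([10.0, 1.0, 0.5, 0.1, 0.0, 3.0])
        for age in (0.5, 5.0, 25.0):
            assert hybrid_gradient(beta, age)[5] == 0.0

    def test_hand_computed_components(self):
        beta = np.array([0.0, 0.0, 0.0, 0.0, 50.0, 2.0])
        grad = hybrid_gradient(beta, 2.0)
        assert grad[4] == pytest.approx(0.6321205588285577, rel=1e-12)
        assert grad[5] == pytest.approx(-9.196986029286058, rel=1e-12)

    def test_non_positive_beta5(self):
        bad = BETA_EXAMPLE.copy()
        bad[5] = -1.0
        with pytest.raises(DomainError):
            hybrid_gradient(bad, 1.0)

    def test_matches_central_finite_differences(self, rng):
        for _ in range(100):
            beta = np.concatenate(
                [rng.uniform(-50, 800, 1), rng.uniform(-20, 20, 3),
                 rng.uniform(10, 500, 1), rng.uniform(0.5, 10, 1)]
            )
            age = rng.uniform(0.5, 30.0)
            analytic = hybrid_gradient(beta, age)
            fd = np.empty(6)
            for i in range(6):
                h = 1e-5 * max(1.0, abs(beta[i]))
                up, dn = beta.copy(), beta.copy()
                up[i] += h
                dn[i] -= h
                fd[i] = (evaluate_hybrid(up, age) - evaluate_hybrid(dn, age)) / (2 * h)
            scale = np.max(np.abs(analytic))
            assert np.allclose(analytic, fd, rtol=1e-6, atol=1e-8 * scale)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFitHybrid:
    def test_zero_noise_recovers_curve(self):
        config = sd.GeneratorConfig(seed=5, sigma={"GMV": 0.0, "WMV": 0.0})
        scans = sd.generate_ft_cohort(config)
        fit = fit_hybrid(scans, "GMV")
        grid = default_age_grid()
        true = config.true_curve("GMV", grid)
        scale = float(np.mean(true))
        assert np.max(np.abs(evaluate_hybrid(fit.beta, grid) - true)) < 1e-6 * scale

    def test_pure_line_matches_ols(self, rng):
        # data generated from beta1-only truth; full-model fit must reproduce
        # the closed-form OLS line on the observed ages in the zero-noise limit
        ages = rng.uniform(1.0, 30.0, 200)
        y = 120.0 + 4.0 * ages
        fit = fit_hybrid_xy(ages, y, "WMV")
        slope, intercept = np.polyfit(ages, y, 1)
        ols_line = intercept + slope * ages
        fitted = evaluate_hybrid(fit.beta, ages)
        assert np.max(np.abs(fitted - ols_line)) < 1e-6 * np.mean(np.abs(ols_line))

    def test_insufficient_data(self, rng):
        ages = rng.uniform(1, 30, 5)
        with pytest.raises(InsufficientDataError):
            fit_hybrid_xy(ages, np.ones(5), "GMV")

    def test_identical_ages(self):
        with pytest.raises(NonIdentifiabilityError):
            fit_hybrid_xy(np.full(50, 5.0), np.arange(50.0), "GMV")

    def test_zero_sensitivity_column_raises(self, rng):
        # beta4 frozen at 0 leaves beta5 with exactly zero gradient
        ages = rng.uniform(1, 30, 100)
        y = 100 + 2 * ages + rng.normal(0, 1, 100)
        with pytest.raises(NonIdentifiabilityError):
            fit_hybrid_xy(ages, y, "GMV", FitSettings(fixed={2: 0.0, 3: 0.0, 4: 0.0}))

    def test_sigma_matches_sse_over_df(self, gmv_fit):
        assert gmv_fit.df == gmv_fit.n_obs - 6
        assert gmv_fit.sigma**2 == pytest.approx(gmv_fit.sse / gmv_fit.df, rel=1e-12)

    def test_param_cov_symmetric_psd(self, gmv_fit):
        cov = gmv_fit.param_cov
        assert np.allclose(cov, cov.T)
        eigvals = np.linalg.eigvalsh(cov)
        assert np.all(eigvals >= -1e-9 * eigvals.max())

    def test_multistart_count_recorded(self, gmv_fit):
        assert gmv_fit.n_starts_tried == len(FitSettings().beta5_starts)
        assert gmv_fit.converged

    def test_ratio_measure_fit(self, ft_scans):
        fit = fit_hybrid(ft_scans, "GMV_over_TIV")
        grid = default_age_grid()
        values = evaluate_hybrid(fit.beta, grid)
        assert np.all((values > 0.2) & (values < 0.8))

    def test_fixed_values_respected(self, rng):
        ages = rng.uniform(1, 30, 150)
        y = 100 + 2 * ages + rng.normal(0, 1, 150)
        fit = fit_hybrid_xy(
            ages, y, "GMV", FitSettings(fixed={2: 0.0, 3: 0.0, 4: 0.0, 5: 1.0})
        )
        assert fit.beta[2] == 0.0 and fit.beta[3] == 0.0 and fit.beta[4] == 0.0
        assert fit.df == 148
        assert np.all(fit.param_cov[2:, :] == 0)

    def test_unknown_measure(self, ft_scans):
        with pytest.raises(DomainError):
            measure_values(ft_scans, "CSF")


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

def make_fit(beta, sigma, cov, n_obs=880, measure="GMV"):
    return GrowthFit(
        measure=measure,
        beta=np.asarray(beta, float),
        sigma=sigma,
        n_obs=n_obs,
        param_cov=np.asarray(cov, float),
        sse=sigma**2 * (n_obs - 6),
        converged=True,
        n_starts_tried=1,
        df=n_obs - 6,
    )


class TestDeltaBands:
    def test_zero_cov_collapses_ci(self):
        fit = make_fit(BETA_EXAMPLE, 5.0, np.zeros((6, 6)))
        band = confidence_band(fit, np.linspace(1, 29, 30))
        assert np.allclose(band.ci_lo, band.mean)
        assert np.allclose(band.ci_hi, band.mean)

    def test_zero_cov_constant_pi_halfwidth(self):
        from scipy import stats

        fit = make_fit(BETA_EXAMPLE, 5.0, np.zeros((6, 6)))
        band = prediction_band(fit, np.linspace(1, 29, 30))
        expected = stats.t.ppf(0.975, fit.df) * 5.0
        assert np.allclose(band.pi_hi - band.mean, expected)
        assert np.allclose(band.mean - band.pi_lo, expected)

    def test_zero_sigma_pi_equals_ci(self):
        config = sd.GeneratorConfig(seed=5, sigma={"GMV": 0.0, "WMV": 0.0})
        scans = sd.generate_ft_cohort(config)
        fit = fit_hybrid(scans, "GMV")
        band = prediction_band(fit, default_age_grid())
        scale = float(np.mean(band.mean))
        assert np.max(np.abs(band.pi_hi - band.ci_hi)) < 1e-6 * scale
        assert np.max(np.abs(band.pi_lo - band.ci_lo)) < 1e-6 * scale

    def test_band_ordering(self, gmv_band):
        assert np.all(gmv_band.pi_lo <= gmv_band.ci_lo)
        assert np.all(gmv_band.ci_lo <= gmv_band.mean)
        assert np.all(gmv_band.mean <= gmv_band.ci_hi)
        assert np.all(gmv_band.ci_hi <= gmv_band.pi_hi)

    def test_delta_band_symmetric(self, gmv_band):
        assert np.allclose(
            gmv_band.ci_hi - gmv_band.mean, gmv_band.mean - gmv_band.ci_lo
        )
        assert np.allclose(
            gmv_band.pi_hi - gmv_band.mean, gmv_band.mean - gmv_band.pi_lo
        )

    def test_unconverged_fit_rejected(self, gmv_fit):
        import dataclasses

        broken = dataclasses.replace(gmv_fit, converged=False)
        with pytest.raises(StateError):
            confidence_band(broken, default_age_grid())

    def test_bad_level(self, gmv_fit):
        with pytest.raises(DomainError):
            confidence_band(gmv_fit, default_age_grid(), level=1.5)

    def test_ci_shrinks_with_n(self):
        interior = np.arange(3.0, 28.0, 1.0)
        halfwidths = {}
        for n in (250, 4000):
            config = sd.GeneratorConfig(seed=77, n_subjects=n)
            fit = fit_hybrid(sd.generate_ft_cohort(config), "GMV")
            band = confidence_band(fit, interior)
            halfwidths[n] = band.ci_hi - band.mean
        assert np.all(halfwidths[4000] < halfwidths[250])

    def test_level_ordering(self, gmv_fit):
        grid = default_age_grid()
        narrow = confidence_band(gmv_fit, grid, 0.80)
        wide = confidence_band(gmv_fit, grid, 0.99)
        assert np.all(narrow.ci_hi <= wide.ci_hi)


class TestMonteCarloBand:
    def test_degenerate_inputs_collapse(self):
        fit = make_fit(BETA_EXAMPLE, 0.0, np.zeros((6, 6)))
        band = mc_band(fit, np.linspace(1, 29, 15), n_draws=2000, seed=1)
        assert np.allclose(band.ci_lo, band.mean)
        assert np.allclose(band.pi_hi, band.mean)

    def test_seed_determinism(self, gmv_fit):
        ages = np.arange(5.0, 25.0, 2.0)
        first = mc_band(gmv_fit, ages, n_draws=2000, seed=9)
        second = mc_band(gmv_fit, ages, n_draws=2000, seed=9)
        for field in ("mean", "ci_lo", "ci_hi", "pi_lo", "pi_hi"):
            assert np.array_equal(getattr(first, field), getattr(second, field))

    def test_different_seed_differs(self, gmv_fit):
        ages = np.arange(5.0, 25.0, 2.0)
        first = mc_band(gmv_fit, ages, n_draws=2000, seed=9)
        second = mc_band(gmv_fit, ages, n_draws=2000, seed=10)
        assert not np.array_equal(first.ci_lo, second.ci_lo)

    def test_min_draws(self, gmv_fit):
        with pytest.raises(DomainError):
            mc_band(gmv_fit, np.arange(5.0, 25.0), n_draws=10, seed=0)

    def test_ordering_invariant(self, gmv_fit):
        band = mc_band(gmv_fit, default_age_grid(), n_draws=2000, seed=3)
        assert np.all(band.pi_lo <= band.ci_lo)
        assert np.all(band.ci_hi <= band.pi_hi)
        assert np.all(band.ci_lo <= band.mean)

    def test_excessive_rejection_raises(self):
        # a symmetric Gaussian centered at beta5 > 0 rejects at most half its
        # draws, so the guard is exercised with a stub generator whose draws
        # always violate the bound
        from voltraj.normative_model import _draw_beta

        class AlwaysNegative:
            def standard_normal(self, shape):
                return np.full(shape, -1e6)

        cov = np.zeros((6, 6))
        cov[5, 5] = 1.0
        fit = make_fit([100, 0, 0, 0, 50, 0.01], 1.0, cov)
        with pytest.raises(PropagationError):
            _draw_beta(fit, 2000, AlwaysNegative())

    def test_agrees_with_delta_on_well_conditioned_fit(self):
        config = sd.GeneratorConfig(seed=11, sigma={"GMV": 20.0, "WMV": 20.0})
        fit = fit_hybrid(sd.generate_ft_cohort(config), "GMV")
        interior = np.arange(5.0, 25.5, 1.0)
        delta = confidence_band(fit, interior)
        mc = mc_band(fit, interior, n_draws=10_000, seed=42)
        for lo, hi in (("ci_lo", "ci_hi"), ("pi_lo", "pi_hi")):
            ratio = (getattr(mc, hi) - getattr(mc, lo)) / (
                getattr(delta, hi) - getattr(delta, lo)
            )
            assert np.all(np.abs(ratio - 1.0) < 0.10)


# ---------------------------------------------------------------------------
# Scan I/O
# ---------------------------------------------------------------------------

class TestScanIO:
    def test_round_trip(self, tmp_path, ft_scans):
        path = tmp_path / "scans.csv"
        write_scans(ft_scans[:25], path)
        loaded = read_scans(path)
        assert len(loaded) == 25
        assert loaded[0].subject_id == ft_scans[0].subject_id
        assert loaded[3].gmv_cm3 == pytest.approx(ft_scans[3].gmv_cm3)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,age_years\nA,5\n")
        from voltraj.errors import SchemaError

        with pytest.raises(SchemaError):
            read_scans(path)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"age_years": 0.0},
            {"age_years": 150.0},
            {"sex": "other"},
            {"gmv_cm3": -1.0},
            {"tiv_cm3": 1000.0},
        ],
    )
    def test_scan_validation(self, overrides):
        base = dict(
            subject_id="S1",
            dataset="C-MIND",
            age_years=10.0,
            sex="female",
            tiv_cm3=1400.0,
            gmv_cm3=700.0,
            wmv_cm3=450.0,
        )
        base.update(overrides)
        with pytest.raises(DomainError):
            IndividualScan(**base).validate()
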