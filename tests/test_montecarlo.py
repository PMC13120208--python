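"""Distribution sampling, lognormal fitting, and Monte Carlo propagation."""

import numpy as np
import pytest

from nanorisk import DistributionSpec, ExposureFactorSet, PODS, fit_lognormal, sample
from nanorisk.assessment import risk_chain_model, simulate_risk
from nanorisk.errors import (
    ConfigurationError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidSpecError,
)
from nanorisk.montecarlo import run_simulation, uniform_fit_aic


class TestDistributionSpec:
    def test_point_is_degenerate(self):
        np.testing.assert_array_equal(sample(DistributionSpec.point(5.0), 3, 0),
                                      [5.0, 5.0, 5.0])

    def test_triangular_mean_recovered(self):
        draws = sample(DistributionSpec.triangular(5, 6, 8), 10_000, 42)
        mean = (5 + 6 + 8) / 3
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se
        assert draws.min() >= 5 and draws.max() <= 8

    def test_uniform_support(self):
        spec = DistributionSpec.uniform_pm(65.2, 0.3)
        draws = sample(spec, 5_000, 7)
        assert draws.min() >= 64.9 and draws.max() <= 65.5

    def test_lognormal_support_and_median(self):
        spec = DistributionSpec.lognormal(3.99, 2.0)
        draws = sample(spec, 20_000, 11)
        assert np.all(draws > 0)
        assert np.median(draws) == pytest.approx(3.99, rel=0.05)
        assert spec.median() == pytest.approx(3.99)

    @pytest.mark.parametrize(
        "family, params",
        [
            ("triangular", {"minimum": 6, "mode": 5, "maximum": 8}),
            ("uniform", {"low": 2.0, "high": 1.0}),
            ("lognormal", {"gm": -1.0, "gsd": 2.0}),
            ("lognormal", {}),
            ("cauchy", {"scale": 1.0}),
        ],
    )
    def test_invalid_specs_rejected(self, family, params):
        with pytest.raises(InvalidSpecError):
            DistributionSpec(family, params)

    def test_seed_reproducibility(self):
        spec = DistributionSpec.lognormal(1.0, 1.8)
        np.testing.assert_array_equal(sample(spec, 100, 3), sample(spec, 100, 3))
        assert not np.array_equal(sample(spec, 100, 3), sample(spec, 100, 4))


class TestFitLognormal:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(123)
        data = np.exp(rng.standard_normal(5_000))
        fit = fit_lognormal(data)
        assert abs(fit.mu) < 0.05
        assert abs(fit.sigma - 1.0) < 0.05
        assert fit.chi_square_dof == 7

    def test_degenerate_input(self):
        with pytest.raises(DegenerateFitError):
            fit_lognormal(np.full(100, 3.0))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_lognormal([1.0, 2.0, 3.0])

    def test_model_selection_prefers_true_family(self):
        rng = np.random.default_rng(9)
        data = np.exp(rng.normal(0.0, 1.0, size=2_000))
        assert fit_lognormal(data).aic <= uniform_fit_aic(data)

    def test_chi_square_small_for_well_specified_model(self):
        rng = np.random.default_rng(5)
        data = np.exp(rng.normal(1.0, 0.5, size=5_000))
        fit = fit_lognormal(data)
        # chi-square ~ chi2(7) for a correct model: far below gross misfit
        assert fit.chi_square < 30


class TestRunSimulation:
    def test_degenerate_specs_collapse_to_deterministic_chain(self):
        f = ExposureFactorSet.male()
        model = risk_chain_model(f, PODS["silver"], 0.19,
                                 concentration_adjusted=True)
        specs = {"c": DistributionSpec.point(0.301),
                 "et": DistributionSpec.point(6),
                 "ef": DistributionSpec.point(63),
                 "ed": DistributionSpec.point(25),
                 "bw": DistributionSpec.point(65.2),
                 "ir": DistributionSpec.point(17.48)}
        summaries, _ = run_simulation(model, specs, n=500, seed=0)
        hq = summaries["hq"]
        assert hq.mean == hq.p50 == hq.p95 == pytest.approx(1.58, rel=5e-3)
        assert hq.sd == 0.0
        det = model(0.301, 6, 63, 25, 65.2, 17.48)
        for name in ("cdi", "cdi_25", "cdi_adj", "moe"):
            s = summaries[name]
            assert s.sd == 0.0
            assert s.mean == pytest.approx(float(det[name]), rel=1e-12)

    def test_unbound_symbols_rejected(self):
        f = ExposureFactorSet.male()
        model = risk_chain_model(f)
        with pytest.raises(ConfigurationError):
            run_simulation(model, {}, n=10, seed=0)
        with pytest.raises(ConfigurationError):
            run_simulation(model, {"c": DistributionSpec.point(1.0)}, n=10, seed=0)

    def test_seed_reproducibility_bit_for_bit(self):
        f = ExposureFactorSet.female()
        a, _ = simulate_risk(DistributionSpec.lognormal(3.99, 2.0), f,
                             PODS["silver"], 0.19, n=2_000, seed=5)
        b, _ = simulate_risk(DistributionSpec.lognormal(3.99, 2.0), f,
                             PODS["silver"], 0.19, n=2_000, seed=5)
        for name in a:
            np.testing.assert_array_equal(a[name].samples, b[name].samples)
            assert a[name].mean == b[name].mean

    def test_monotone_transform_quantile_identity(self):
        """With only C random and a monotone chain, p50(MoE) = MoE(median C)."""
        f = ExposureFactorSet.male()
        c_spec = DistributionSpec.lognormal(3.99, 2.0)
        specs = {"c": c_spec,
                 "et": DistributionSpec.point(6),
                 "ef": DistributionSpec.point(63),
                 "ed": DistributionSpec.point(25),
                 "bw": DistributionSpec.point(65.2),
                 "ir": DistributionSpec.point(17.48)}
        model = risk_chain_model(f, PODS["silver"], 0.19)
        summaries, draws = run_simulation(model, specs, n=10_000, seed=17)
        det = model(c_spec.median(), 6, 63, 25, 65.2, 17.48)
        moe = summaries["moe"].samples
        # 3 MC standard errors of the sample median (asymptotic normal)
        se = 1.2533 * moe.std(ddof=1) / np.sqrt(moe.size)
        assert abs(summaries["moe"].p50 - float(det["moe"])) < 3 * se

    def test_p50_convergence_across_seeds(self):
        f = ExposureFactorSet.male()
        p50 = [simulate_risk(DistributionSpec.lognormal(3.99, 2.0), f,
                             PODS["silver"], 0.19, n=10_000, seed=s)[0]["moe"].p50
               for s in range(10)]
        p50 = np.asarray(p50)
        assert p50.std(ddof=1) / p50.mean() < 0.02
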