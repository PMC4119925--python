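import numpy as np
import pytest

import lethaldose as ld
from lethaldose.lddose import BootstrapSummary, LethalDoseEstimate, _invert_survival


def _summary(draws_a, draws_b=None, d_max=100.0, censored_a=None, censored_b=None):
    """Hand-built bootstrap summary for interval/contrast unit tests."""
    draws_a = np.asarray(draws_a, dtype=float)
    strains = ["A"] if draws_b is None else ["A", "B"]
    draws = {("A", 0.5): draws_a}
    cens = {("A", 0.5): np.zeros(len(draws_a), bool) if censored_a is None
            else np.asarray(censored_a, bool)}
    point = {("A", 0.5): LethalDoseEstimate("A", 0.5, float(np.median(draws_a)), False)}
    if draws_b is not None:
        draws_b = np.asarray(draws_b, dtype=float)
        draws[("B", 0.5)] = draws_b
        cens[("B", 0.5)] = (np.zeros(len(draws_b), bool) if censored_b is None
                            else np.asarray(censored_b, bool))
        point[("B", 0.5)] = LethalDoseEstimate("B", 0.5, float(np.median(draws_b)), False)
    return BootstrapSummary(
        n_boot=len(draws_a), n_failed=0, seed=0, levels=(0.5,), strains=strains,
        draws=draws, censored=cens, d_max={s: d_max for s in strains}, point=point,
    )


class TestSurvivalCurve:
    def test_baseline_identity(self, default_fit):
        assert ld.survival_curve(default_fit, "strainA", [0.0])[0] == 1.0

    def test_flat_fit_curve_is_unity(self, flat_fit):
        frac = ld.survival_curve(flat_fit, "A", np.linspace(0.0, 40.0, 60))
        np.testing.assert_allclose(frac, 1.0, atol=1e-8)

    def test_matches_coefficient_level_computation(self, default_fit):
        # independent route: evaluate the centred basis and coefficients directly
        from scipy.interpolate import BSpline

        sm = default_fit.design.smooths["strainA"]
        gamma = sm.transform @ default_fit.coefficients[sm.cols]
        spl = BSpline(sm.knots, gamma, sm.degree)
        d = np.linspace(0.0, 100.0, 41)  # within the observed dose range
        expected = np.exp(spl(np.sqrt(d)) - spl(0.0))
        np.testing.assert_allclose(
            ld.survival_curve(default_fit, "strainA", d), expected, rtol=1e-10
        )

    def test_unknown_strain_raises(self, default_fit):
        with pytest.raises(KeyError):
            ld.survival_curve(default_fit, "nope", [0.0])


class TestInversion:
    def test_exponential_closed_forms(self):
        curve = lambda d: np.exp(-np.log(2.0) * np.asarray(d))
        assert _invert_survival(curve, 0.5, 10.0) == pytest.approx(1.0, abs=1e-5)
        assert _invert_survival(curve, 0.1, 10.0) == pytest.approx(
            np.log(10.0) / np.log(2.0), abs=1e-4
        )

    def test_flat_curve_has_no_crossing(self):
        assert _invert_survival(lambda d: np.ones_like(np.asarray(d)), 0.5, 10.0) is None

    def test_agrees_with_brute_force_grid(self):
        # wiggly but decreasing curve; oracle scans a 1e6-point grid
        curve = lambda d: np.exp(
            -0.3 * np.asarray(d) - 0.05 * np.sin(np.asarray(d))
        )
        d_max = 30.0
        for p in (0.5, 0.1, 0.02):
            fine = np.linspace(0.0, d_max, 1_000_000)
            brute = fine[np.argmax(curve(fine) <= p)]
            fast = _invert_survival(curve, p, d_max)
            assert abs(fast - brute) < 1e-4 * d_max

    def test_estimate_ld_level_validation(self, default_fit):
        for p in (0.0, 1.0, -1.0):
            with pytest.raises(ValueError):
                ld.estimate_ld(default_fit, "strainA", p)

    def test_flat_fit_is_censored_at_max_dose(self, flat_fit):
        est = ld.estimate_ld(flat_fit, "A", 0.5)
        assert est.censored and est.ld_value == 40.0

    def test_ld10_exceeds_ld50_on_monotone_fits(self, default_fit):
        for s in default_fit.strains:
            ld50 = ld.estimate_ld(default_fit, s, 0.5)
            ld10 = ld.estimate_ld(default_fit, s, 0.1)
            assert ld10.ld_value >= ld50.ld_value


class TestBootstrap:
    def test_identical_seed_identical_draws(self, default_dataset, default_fit):
        b1 = ld.parametric_bootstrap(default_dataset, default_fit, n_boot=2, seed=5)
        b2 = ld.parametric_bootstrap(default_dataset, default_fit, n_boot=2, seed=5)
        for key in b1.draws:
            np.testing.assert_array_equal(b1.draws[key], b2.draws[key])

    def test_seed_is_mandatory(self, default_dataset, default_fit):
        with pytest.raises(ValueError, match="seed"):
            ld.parametric_bootstrap(default_dataset, default_fit, n_boot=2)

    def test_spread_shrinks_with_count_scale(self):
        """Near-Poisson data: 100x more cells -> much tighter LD draws."""
        spreads = {}
        for baseline in (1e3, 1e5):
            cfg = ld.default_config(
                seed=12, baseline_count=baseline, theta=1e8, experiment_effect_sd=0.0
            )
            ds = ld.simulate_dataset(cfg)
            fit = ld.fit_penalized_nb(ds)
            boot = ld.parametric_bootstrap(ds, fit, levels=(0.5,), n_boot=30, seed=7)
            spreads[baseline] = boot.draws[("strainA", 0.5)].std()
        assert spreads[1e5] < 0.5 * spreads[1e3]

    def test_too_many_failures_is_an_error(self, default_dataset, default_fit, monkeypatch):
        import lethaldose.lddose as L

        def always_fails(*args, **kwargs):
            raise ld.DegenerateFitError("synthetic failure")

        monkeypatch.setattr(L, "_fit_from_design", always_fails)
        with pytest.raises(RuntimeError, match="unstable"):
            ld.parametric_bootstrap(default_dataset, default_fit, n_boot=4, seed=1)


class TestConfidenceIntervals:
    def test_degenerate_draws_collapse_interval(self):
        boot = _summary(np.full(50, 7.5))
        est = ld.ld_confidence_intervals(boot)[0]
        assert (est.ci_low, est.ci_high) == (7.5, 7.5)

    def test_uniform_draws_recover_percentiles(self, rng):
        boot = _summary(rng.uniform(0.0, 1.0, 2000))
        est = ld.ld_confidence_intervals(boot)[0]
        assert est.ci_low == pytest.approx(0.025, abs=0.012)
        assert est.ci_high == pytest.approx(0.975, abs=0.012)

    def test_censored_draws_flag_the_bound(self):
        draws = np.concatenate([np.linspace(1.0, 5.0, 10), np.full(40, 100.0)])
        boot = _summary(draws, censored_a=[False] * 10 + [True] * 40)
        est = ld.ld_confidence_intervals(boot)[0]
        assert est.ci_high_censored and not est.ci_low_censored
        assert est.ci_high == 100.0

    def test_point_inside_interval_on_real_bootstrap(self, default_boot):
        for est in ld.ld_confidence_intervals(default_boot):
            assert est.ci_low <= est.ld_value <= est.ci_high


class TestStrainDifference:
    def test_constant_shift(self):
        a = np.linspace(3.0, 4.0, 30)
        boot = _summary(a + 2.0, a)
        con = ld.strain_difference(boot, "A", "B", 0.5)
        assert con.ci_low == pytest.approx(2.0)
        assert con.ci_high == pytest.approx(2.0)
        assert con.significant

    def test_antisymmetry(self, rng):
        boot = _summary(rng.normal(5, 1, 40), rng.normal(4, 1, 40))
        ab = ld.strain_difference(boot, "A", "B", 0.5)
        ba = ld.strain_difference(boot, "B", "A", 0.5)
        np.testing.assert_allclose(ab.boot_deltas, -ba.boot_deltas)
        assert ab.delta == pytest.approx(-ba.delta)

    def test_half_censored_replicates_excluded_with_warning(self):
        a = np.array([3.0, 3.2, 3.4, 100.0])
        b = np.array([3.1, 3.0, 3.3, 3.2])
        boot = _summary(a, b, censored_a=[False, False, False, True])
        with pytest.warns(UserWarning, match="censored for exactly one"):
            con = ld.strain_difference(boot, "A", "B", 0.5)
        assert con.n_excluded == 1
        assert len(con.boot_deltas) == 3

    def test_significance_definition(self, default_boot):
        strains = default_boot.strains
        for p in default_boot.levels:
            con = ld.strain_difference(default_boot, strains[0], strains[1], p)
            assert con.significant == (con.ci_low > 0 or con.ci_high < 0)
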