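import numpy as np
import pandas as pd
import pytest

import lethaldose as ld
from lethaldose.model import _build_design


def _single_strain_poisson(seed=13, n_dose=50, reps=8, slope=-0.8):
    """Counts with log-mean 5 + slope*sqrt(dose) and Poisson noise."""
    rng = np.random.default_rng(seed)
    doses = np.linspace(0.0, 16.0, n_dose)
    rows = []
    for d in doses:
        mu = np.exp(5.0 + slope * np.sqrt(d))
        for _ in range(reps):
            rows.append(("A", "e1", d, float(rng.poisson(mu))))
    frame = pd.DataFrame(rows, columns=["strain", "experiment", "dose", "count"])
    return ld.ToleranceDataset(frame), doses


class TestFit:
    def test_flat_counts_give_unit_survival_and_tiny_edf(self, flat_fit):
        grid = np.linspace(0.0, 40.0, 50)
        for s in flat_fit.strains:
            np.testing.assert_allclose(
                ld.survival_curve(flat_fit, s, grid), 1.0, atol=1e-6
            )
            # heavy smoothing leaves only the penalty null space (a line,
            # 1 dof after centring)
            assert flat_fit.edf[s] < 1.2

    def test_recovers_known_log_linear_curve(self):
        ds, doses = _single_strain_poisson()
        fit = ld.fit_penalized_nb(ds, lambdas=1e-8)
        eta_hat = fit.linear_predictor("A", "e1", doses)
        eta_true = 5.0 - 0.8 * np.sqrt(doses)
        assert np.max(np.abs(eta_hat - eta_true)) < 0.05
        assert fit.theta > 1e4  # Poisson data: dispersion pushed very high

    def test_count_rescaling_equivariance(self, default_dataset):
        """Unknown-inoculum property of the count model.

        In the Poisson limit with the penalty rescaled alongside the
        counts, rescaling every count by k shifts the intercept by exactly
        log k and leaves every survival fraction unchanged — the inoculum
        size lives entirely in the intercept.  (With estimated θ and
        re-selected λ the equivariance is only approximate; the LD-level
        consequence is checked in the acceptance suite.)
        """
        k = 8
        base = ld.fit_penalized_nb(default_dataset, lambdas=0.05, theta=1e10)
        frame = default_dataset.frame.copy()
        frame["count"] *= k
        scaled = ld.fit_penalized_nb(
            ld.ToleranceDataset(frame), lambdas=0.05 * k, theta=1e10
        )
        shift = scaled.coefficients[0] - base.coefficients[0]
        assert shift == pytest.approx(np.log(k), abs=1e-5)
        grid = np.linspace(0.0, 120.0, 60)
        for s in base.strains:
            np.testing.assert_allclose(
                ld.survival_curve(scaled, s, grid),
                ld.survival_curve(base, s, grid),
                rtol=1e-4,
            )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_penalized_deviance_never_increases(self, seed):
        ds = ld.simulate_dataset(ld.default_config(seed=seed))
        fit = ld.fit_penalized_nb(ds)
        trace = np.asarray(fit.pen_dev_trace)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-8 * (1.0 + np.abs(trace[:-1])))

    def test_all_zero_strain_is_degenerate(self):
        rows = [("A", "e1", d, 0.0) for d in (0.0, 1.0, 5.0)]
        rows += [("B", "e1", d, c) for d, c in ((0.0, 90.0), (1.0, 50.0), (5.0, 10.0))]
        ds = ld.ToleranceDataset(
            pd.DataFrame(rows, columns=["strain", "experiment", "dose", "count"])
        )
        with pytest.raises(ld.DegenerateFitError, match="all-zero"):
            ld.fit_penalized_nb(ds)

    def test_smoothing_selection_is_deterministic(self, default_dataset):
        lam1 = ld.select_smoothing(default_dataset)
        lam2 = ld.select_smoothing(default_dataset)
        assert lam1 == lam2


class TestPrediction:
    def test_consistent_with_stored_fitted_values(self, default_dataset, default_fit):
        frame = default_dataset.frame
        for (s, e), sub in frame.groupby(["strain", "experiment"], sort=False):
            pred = ld.predict_mean(default_fit, s, e, sub["dose"].to_numpy())
            stored = default_fit.fitted[sub.index.to_numpy()]
            np.testing.assert_allclose(pred, stored, rtol=1e-10)

    def test_matches_design_matrix_product(self, default_dataset, default_fit):
        design = default_fit.design
        eta_rows = design.X @ default_fit.coefficients
        for (s, e), sub in default_dataset.frame.groupby(
            ["strain", "experiment"], sort=False
        ):
            eta = default_fit.linear_predictor(s, e, sub["dose"].to_numpy())
            np.testing.assert_allclose(eta, eta_rows[sub.index.to_numpy()], atol=1e-10)

    def test_empty_dose_vector(self, default_fit):
        out = ld.predict_mean(default_fit, "strainA", "exp1", np.array([]))
        assert out.size == 0

    def test_unseen_levels_raise(self, default_fit):
        with pytest.raises(KeyError):
            ld.predict_mean(default_fit, "nope", "exp1", [1.0])
        with pytest.raises(KeyError):
            ld.predict_mean(default_fit, "strainA", "nope", [1.0])

    def test_negative_dose_rejected(self, default_fit):
        with pytest.raises(ValueError):
            ld.predict_mean(default_fit, "strainA", "exp1", [-1.0])

    def test_strictly_positive_and_continuous(self, default_fit):
        grid = np.linspace(0.0, 150.0, 400)  # extends past the observed range
        mu = ld.predict_mean(default_fit, "strainA", "exp1", grid)
        assert np.all(mu > 0)
        log_jumps = np.abs(np.diff(np.log(mu)))
        assert log_jumps.max() < 0.5


class TestRecoveryScaling:
    def test_error_shrinks_with_sample_size(self):
        """Sup-norm error of the fitted log-survival curve drops as data grow."""
        params = ld.ShoulderCurveParams(shoulder=2.0, decay_rate=0.5, smoothness=0.1)
        doses = np.asarray(ld.DOSE_GRIDS["chemical"])
        eval_doses = doses[doses <= 20.0]
        log_s_true = np.log(ld.shoulder_survival(params, eval_doses))
        errors = {}
        for reps in (2, 25):  # 32 vs 400 observations per strain pair
            errs = []
            for seed in range(100):
                cfg = ld.default_config(seed=seed, plate_replicates=reps)
                fit = ld.fit_penalized_nb(ld.simulate_dataset(cfg))
                curve = np.log(ld.survival_curve(fit, "strainA", eval_doses))
                errs.append(np.max(np.abs(curve - log_s_true)))
            errors[reps] = np.median(errs)
        assert errors[25] < errors[2]


class TestModelSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "model.yaml"
        path.write_text(
            "num_basis: 6\ndegree: 2\npenalty_order: 1\n"
            "lambda_grid: [0.1, 1.0, 10.0]\ntheta_init: 2.5\ncriterion: aicc\n"
        )
        spec = ld.load_model_spec(path)
        assert spec.basis.num_basis == 6
        assert spec.basis.degree == 2
        assert spec.basis.penalty_order == 1
        assert spec.lambda_grid == (0.1, 1.0, 10.0)
        assert spec.theta_init == 2.5
        assert spec.criterion == "aicc"

    def test_empty_yaml_gives_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        spec = ld.load_model_spec(path)
        assert spec.basis.num_basis == 8
        assert spec.criterion == "laml"

    def test_design_dimensions(self, default_dataset):
        design = _build_design(default_dataset, ld.ModelSpec())
        # intercept + 1 strain dummy + 2 nested experiment dummies
        assert design.n_param == 4
        # two centred 8-function smooths contribute 7 columns each
        assert design.p == 4 + 14
        assert design.n == len(default_dataset)
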