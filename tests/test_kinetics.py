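"""Removal efficiency, uptake bookkeeping and kinetic model fits."""

import numpy as np
import pytest
from scipy import stats

from sorbopt import (
    KineticTrace,
    fit_pseudo_first_order,
    fit_pseudo_second_order,
    generate_kinetic_trace,
    qt_series,
    removal_efficiency,
)
from sorbopt.datasets import PB_KINETIC_PARAMETERS
from sorbopt.errors import InsufficientDataError, InvalidFitError, ValidationError

TIMES = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0])
BATCH = dict(c0=10.0, volume_l=0.05, mass_g=0.075)  # 1.5 g/L dose


class TestRemovalEfficiency:
    @pytest.mark.parametrize(
        "ci, cf, expected",
        [(10.0, 0.0, 100.0), (10.0, 10.0, 0.0), (10.0, 0.29, 97.1)],
    )
    def test_values(self, ci, cf, expected):
        assert removal_efficiency(ci, cf) == pytest.approx(expected)

    def test_rejects_nonpositive_initial(self):
        with pytest.raises(ValidationError):
            removal_efficiency(0.0, 1.0)

    def test_negative_efficiency_returned_not_raised(self):
        assert removal_efficiency(10.0, 12.0) == pytest.approx(-20.0)


class TestQtSeries:
    def test_published_magnitude(self):
        trace = KineticTrace(
            times=np.array([0.0, 100.0]),
            concentrations=np.array([10.0, 4.41]),
            **BATCH,
        )
        assert qt_series(trace)[-1] == pytest.approx(3.727, abs=1e-3)

    def test_no_uptake_gives_zeros(self):
        trace = KineticTrace(
            times=np.array([0.0, 10.0]), concentrations=np.array([10.0, 10.0]), **BATCH
        )
        assert np.allclose(qt_series(trace), 0.0)

    def test_linearity_in_concentration_drop(self):
        t = np.array([0.0, 10.0, 20.0])
        a = KineticTrace(times=t, concentrations=np.array([10.0, 9.0, 8.0]), **BATCH)
        b = KineticTrace(times=t, concentrations=np.array([10.0, 8.0, 6.0]), **BATCH)
        assert np.allclose(2 * qt_series(a), qt_series(b))

    def test_consistency_with_removal_efficiency(self):
        trace = KineticTrace(
            times=TIMES, concentrations=10.0 - 0.05 * TIMES, **BATCH
        )
        qt = qt_series(trace)
        r = removal_efficiency(trace.c0, trace.concentrations)
        assert np.allclose(
            r, 100.0 * trace.mass_g * qt / (trace.volume_l * trace.c0)
        )

    def test_trace_validation(self):
        with pytest.raises(ValidationError):
            KineticTrace(times=np.array([0.0, 0.0]), concentrations=np.array([10.0, 9.0]), **BATCH)
        with pytest.raises(ValidationError):
            KineticTrace(times=np.array([0.0, 1.0]), concentrations=np.array([10.0, 11.0]), **BATCH)
        with pytest.raises(ValidationError):
            KineticTrace(times=np.array([0.0, 1.0]), concentrations=np.array([10.0, 9.0]),
                         c0=10.0, volume_l=0.05, mass_g=0.0)


class TestPseudoFirstOrder:
    def test_noiseless_round_trip_to_four_figures(self):
        qe, k1 = PB_KINETIC_PARAMETERS["qe_exp"], PB_KINETIC_PARAMETERS["first"]["k1"]
        qt = qe * (1.0 - np.exp(-k1 * TIMES))
        fit = fit_pseudo_first_order(TIMES, qt, qe_exp=qe)
        assert fit.rate_constant == pytest.approx(k1, rel=1e-4)
        assert fit.qe_calc == pytest.approx(qe, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_line_slope_identity(self):
        qe, k1 = 3.727, 0.0879
        qt = qe * (1.0 - np.exp(-k1 * TIMES))
        fit = fit_pseudo_first_order(TIMES, qt, qe_exp=qe)
        slope = stats.linregress(TIMES, np.log10(qe - qt)).slope
        assert fit.rate_constant == pytest.approx(-slope * np.log(10.0))

    def test_points_at_plateau_excluded(self):
        qe = 2.0
        qt = np.array([0.5, 1.0, 1.5, 1.9, 2.0, 2.1])
        t = np.arange(1.0, 7.0)
        fit = fit_pseudo_first_order(t, qt, qe_exp=qe)
        assert fit.n_excluded == 2
        assert fit.n_used == 4

    def test_too_few_usable_points(self):
        with pytest.raises(InsufficientDataError):
            fit_pseudo_first_order(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.5]), qe_exp=2.0)


class TestPseudoSecondOrder:
    def test_noiseless_round_trip_to_four_figures(self):
        qe, k2 = (PB_KINETIC_PARAMETERS["second"]["qe_calc"],
                  PB_KINETIC_PARAMETERS["second"]["k2"])
        qt = qe**2 * k2 * TIMES / (1.0 + qe * k2 * TIMES)
        fit = fit_pseudo_second_order(TIMES, qt)
        assert fit.qe_calc == pytest.approx(qe, rel=1e-4)
        assert fit.rate_constant == pytest.approx(k2, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_line_slope_identity(self):
        qe, k2 = 3.782, 0.1148
        qt = qe**2 * k2 * TIMES / (1.0 + qe * k2 * TIMES)
        fit = fit_pseudo_second_order(TIMES, qt)
        slope = stats.linregress(TIMES, TIMES / qt).slope
        assert fit.qe_calc == pytest.approx(1.0 / slope)

    def test_second_order_data_prefers_second_order_model(self):
        qe, k2 = 3.782, 0.1148
        qt = qe**2 * k2 * TIMES / (1.0 + qe * k2 * TIMES)
        second = fit_pseudo_second_order(TIMES, qt)
        first = fit_pseudo_first_order(TIMES, qt, qe_exp=float(qt[-1]) * 1.001)
        assert second.r_squared > first.r_squared

    def test_inapplicable_model_raises(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(InvalidFitError):
            fit_pseudo_second_order(t, np.array([4.0, 2.0, 1.3, 1.0]))


class TestNoisyRecovery:
    @pytest.mark.parametrize("model", ["first", "second"])
    def test_relative_error_under_one_percent_noise(self, model):
        # sigma on C_t chosen so the induced q_t noise is 1% of q_e; the
        # first-order trace is sampled before its plateau, where
        # log(qe - q_t) still carries signal above the noise floor
        if model == "first":
            qe, k = 3.0, PB_KINETIC_PARAMETERS["first"]["k1"]
            times = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0])
        else:
            qe, k = 3.0, PB_KINETIC_PARAMETERS["second"]["k2"]
            times = TIMES
        sigma_c = 0.01 * qe * BATCH["mass_g"] / BATCH["volume_l"]
        rng = np.random.default_rng(123)
        errs_qe, errs_k = [], []
        for _ in range(100):
            trace = generate_kinetic_trace(
                model, qe=qe, k=k, times=times, sigma=sigma_c, rng=rng, **BATCH
            )
            qt = qt_series(trace)
            if model == "first":
                fit = fit_pseudo_first_order(trace.times, qt, qe_exp=qe)
            else:
                fit = fit_pseudo_second_order(trace.times, qt)
            errs_qe.append(abs(fit.qe_calc - qe) / qe)
            errs_k.append(abs(fit.rate_constant - k) / k)
        assert np.mean(errs_qe) < 0.10
        assert np.mean(errs_k) < 0.10
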