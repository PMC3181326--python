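"""Trace quantification: sigma, histograms, mixtures, I–V and delta_U fits."""

import math

import numpy as np
import pytest

from leafletshift.analysis import (
    MixtureComponent,
    SigmaCurve,
    build_histogram,
    current_sigma,
    estimate_delta_u,
    extract_level_currents,
    fit_iv,
    fit_mixture,
    fit_sigma_concentration,
    fit_sigma_voltage,
    relative_change,
    substate_probabilities,
)
from leafletshift.electrostatics import stern_sds_adsorption
from leafletshift.gating import DEFAULT_MODEL, expected_sigma
from leafletshift.traceio import TraceRecording


def make_trace(currents, v=-60.0, fs=20.0):
    return TraceRecording(
        currents=np.asarray(currents, dtype=float), sampling_rate=fs, v_applied=v
    )


class TestCurrentSigma:
    def test_constant_trace_has_zero_sigma(self):
        assert current_sigma(make_trace(np.full(100, -3.0))) == 0.0

    def test_gaussian_trace_recovers_noise_scale(self, rng):
        rec = make_trace(rng.normal(0.0, 2.5, size=100_000))
        assert current_sigma(rec) == pytest.approx(2.5, rel=0.02)

    def test_two_level_trace_matches_bernoulli_closed_form(self):
        # occupancy q at amplitude -A gives sd A*sqrt(q(1-q))
        n, q, amplitude = 200_000, 0.3, 20.0
        currents = np.zeros(n)
        currents[: int(q * n)] = -amplitude
        expected = amplitude * math.sqrt(q * (1 - q))
        assert current_sigma(make_trace(currents)) == pytest.approx(
            expected, rel=1e-5
        )

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            current_sigma(make_trace([1.0]))


class TestHistogram:
    def test_unit_integral_and_bin_count(self, rng):
        rec = make_trace(rng.normal(0, 1, 5000))
        hist = build_histogram(rec)
        integral = np.sum(hist.densities * np.diff(hist.bin_edges))
        assert integral == pytest.approx(1.0, abs=1e-9)
        assert len(hist.densities) >= 50

    def test_mode_bin_captures_dominant_value(self, rng):
        x = np.concatenate([np.full(9000, -5.0), rng.normal(0, 0.5, 1000)])
        hist = build_histogram(make_trace(x))
        widths = np.diff(hist.bin_edges)
        mode = np.argmax(hist.densities)
        assert hist.densities[mode] * widths[mode] >= 0.9

    def test_matches_analytic_mixture_density(self, rng):
        n = 1_000_000
        weights, means, sd = (0.6, 0.4), (0.0, -30.0), 1.5
        labels = rng.random(n) < weights[1]
        x = rng.normal(np.where(labels, means[1], means[0]), sd)
        hist = build_histogram(make_trace(x))
        centers = 0.5 * (hist.bin_edges[1:] + hist.bin_edges[:-1])
        analytic = sum(
            w * np.exp(-0.5 * ((centers - m) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
            for w, m in zip(weights, means)
        )
        assert np.max(np.abs(hist.densities - analytic)) <= 0.05

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(make_trace(np.zeros(1000)))


class TestMixture:
    def test_single_gaussian_gives_one_component(self, rng):
        rec = make_trace(rng.normal(-2.0, 1.0, 50_000))
        comps = fit_mixture(rec, k_max=4)
        assert len(comps) == 1
        assert comps[0].weight == pytest.approx(1.0, abs=1e-9)
        assert comps[0].mean == pytest.approx(-2.0, abs=0.05)

    def test_two_component_weights_recovered(self, rng):
        n = 200_000
        labels = rng.random(n) < 0.3
        x = rng.normal(np.where(labels, -30.0, 0.0), 1.0)
        comps = fit_mixture(make_trace(x), k_max=4)
        assert len(comps) == 2
        assert comps[0].weight == pytest.approx(0.7, abs=0.02)
        assert comps[1].weight == pytest.approx(0.3, abs=0.02)
        assert comps[1].mean == pytest.approx(-30.0, abs=0.1)

    def test_close_components_merge_into_convolved_peak(self, rng):
        # separation below merge_sd_factor * sd: reported as one (0,1) peak
        n = 100_000
        labels = rng.random(n) < 0.4
        x = rng.normal(np.where(labels, -2.0, 0.0), 1.5)
        comps = fit_mixture(make_trace(x), k_max=4, merge_sd_factor=3.0)
        assert len(comps) == 1
        assert comps[0].weight == pytest.approx(1.0, abs=1e-9)
        assert comps[0].merged_labels in ({0}, {0, 1})


class TestSubstateProbabilities:
    def test_single_closed_component(self):
        comps = [MixtureComponent(weight=1.0, mean=0.0, sd=1.0,
                                  merged_labels=frozenset({0}))]
        probs = substate_probabilities(comps, np.array([0.0, -5.4, -22.2, -62.4]))
        assert probs.groups == {(0, 1, 2, 3): 1.0}

    def test_three_component_probabilities_equal_weights(self):
        comps = [
            MixtureComponent(0.7, 0.0, 1.0, frozenset({0})),
            MixtureComponent(0.2, -22.2, 1.0, frozenset({1})),
            MixtureComponent(0.1, -62.4, 1.0, frozenset({2})),
        ]
        probs = substate_probabilities(comps, np.array([0.0, -5.4, -22.2, -62.4]))
        assert probs.probability(0, 1) == pytest.approx(0.7)
        assert probs.probability(2) == pytest.approx(0.2)
        assert probs.probability(3) == pytest.approx(0.1)
        assert probs.probability_at_least(2) == pytest.approx(0.3)

    def test_ambiguous_assignment_rejected(self):
        comps = [
            MixtureComponent(0.5, -20.0, 1.0, frozenset({0})),
            MixtureComponent(0.5, -21.0, 1.0, frozenset({1})),
        ]
        with pytest.raises(ValueError, match="ambiguous"):
            substate_probabilities(comps, np.array([0.0, -20.5]))


class TestRelativeChange:
    @pytest.mark.parametrize(
        "p0, p1, expected", [(0.5, 0.5, 0.0), (0.5, 0.23, -54.0), (0.5, 0.87, 74.0)]
    )
    def test_percent_arithmetic(self, p0, p1, expected):
        assert relative_change(p0, p1) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 0.5)


class TestExtractLevelCurrents:
    def _components(self):
        return [
            MixtureComponent(0.8, 0.0, 1.0, frozenset({0})),
            MixtureComponent(0.2, -30.0, 1.0, frozenset({1})),
        ]

    def test_closed_only_trace_flags_open_levels(self, rng):
        rec = make_trace(rng.normal(0, 1, 2000))
        readings = extract_level_currents(rec, self._components(), min_readings=20)
        assert (1,) in readings.unusable
        assert readings.readings[(1,)].size == 0

    def test_dwell_means_recover_level_current(self, rng):
        # 50 dwells of 40 samples at -30 pA separated by closed stretches
        pieces = []
        for _ in range(50):
            pieces.append(rng.normal(0, 1, 100))
            pieces.append(rng.normal(-30.0, 1, 40))
        rec = make_trace(np.concatenate(pieces))
        readings = extract_level_currents(rec, self._components(), min_readings=20)
        vals = readings.readings[(1,)]
        assert vals.size >= 45
        assert np.mean(vals) == pytest.approx(-30.0, abs=3 * 1.0 / math.sqrt(40 * 45))
        assert (1,) not in readings.unusable

    def test_short_runs_do_not_count_as_readings(self, rng):
        # dwells of 3 samples are below the 5-sample idealization floor
        pieces = []
        for _ in range(30):
            pieces.append(rng.normal(0, 0.5, 50))
            pieces.append(np.full(3, -30.0))
        rec = make_trace(np.concatenate(pieces))
        readings = extract_level_currents(rec, self._components(), min_readings=20)
        assert readings.readings[(1,)].size == 0
        assert (1,) in readings.unusable


class TestFitIV:
    def test_exact_line_recovered_with_zero_sem(self):
        points = [(v, 0.37 * v) for v in (-40.0, -50.0, -60.0, -70.0)]
        fit = fit_iv(points)
        assert fit.slope == pytest.approx(0.37, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_sem == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.uniform(-80, -30, 40)
        i = 0.9 * v + rng.normal(0, 2.0, 40)
        fit = fit_iv(list(zip(v, i)))
        design = np.column_stack([np.ones_like(v), v])
        beta = np.linalg.solve(design.T @ design, design.T @ i)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-12)
        assert fit.slope == pytest.approx(abs(beta[1]), abs=1e-12)

    def test_rank_deficient_input_rejected(self):
        with pytest.raises(ValueError):
            fit_iv([(-50.0, -18.5), (-50.0, -18.4)])


class TestSigmaVoltageFit:
    def test_exact_exponential_curve_recovered(self):
        curve = SigmaCurve(
            points=tuple((-v, 0.5 * math.exp(0.1 * v)) for v in (40, 50, 60, 70))
        )
        fit = fit_sigma_voltage(curve)
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(math.log(0.5), abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_curve_has_zero_slope(self):
        curve = SigmaCurve(points=tuple((-v, 2.0) for v in (40, 50, 60)))
        assert fit_sigma_voltage(curve).slope == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_voltages_and_positive_sigma(self):
        with pytest.raises(ValueError):
            fit_sigma_voltage(SigmaCurve(points=((-40.0, 1.0), (-50.0, 2.0))))
        with pytest.raises(ValueError):
            SigmaCurve(points=((-40.0, 0.0),))


class TestEstimateDeltaU:
    @staticmethod
    def _drive_curve(shift, volts=(40, 45, 50, 55, 60, 65), slope=0.1):
        # sigma = |V| * A * exp(b (|V| + shift)): ohmic amplitude times
        # exponential activity in the driving potential
        return SigmaCurve(
            points=tuple(
                (-v, v * 0.05 * math.exp(slope * (v + shift))) for v in volts
            )
        )

    def test_identical_curves_give_zero_shift(self):
        c = self._drive_curve(0.0)
        est = estimate_delta_u(c, c)
        assert est.delta_u == pytest.approx(0.0, abs=1e-9)

    def test_constructed_shift_recovered_exactly(self):
        est = estimate_delta_u(self._drive_curve(0.0), self._drive_curve(5.0))
        assert est.delta_u == pytest.approx(5.0, abs=1e-8)
        assert est.sem == pytest.approx(0.0, abs=1e-6)

    def test_antisymmetric_under_condition_swap(self):
        control = self._drive_curve(0.0)
        treated = self._drive_curve(3.7)
        forward = estimate_delta_u(control, treated)
        backward = estimate_delta_u(treated, control)
        assert backward.delta_u == pytest.approx(-forward.delta_u, abs=1e-10)

    def test_non_overlapping_voltage_ranges_rejected(self):
        low = self._drive_curve(0.0, volts=(40, 45, 50))
        high = self._drive_curve(0.0, volts=(80, 85, 90))
        with pytest.raises(ValueError, match="overlap"):
            estimate_delta_u(low, high)

    def test_vanishing_common_slope_rejected(self):
        flat = SigmaCurve(points=tuple((-v, 2.0) for v in (40, 50, 60)))
        with pytest.raises(ValueError, match="slope"):
            estimate_delta_u(flat, flat, drive_exponent=0.0)

    def test_bootstrap_sem_available_for_long_curves(self, rng):
        control = self._drive_curve(0.0)
        noisy = SigmaCurve(
            points=tuple(
                (v, s * math.exp(rng.normal(0, 0.03)))
                for v, s in self._drive_curve(5.0).points
            )
        )
        est = estimate_delta_u(control, noisy, method="bootstrap", seed=5)
        assert est.method["sem_method"].startswith("bootstrap")
        assert 0.0 < est.sem < 3.0
        assert est.delta_u == pytest.approx(5.0, abs=1.5)


class TestSimulatedRecovery:
    """End-to-end parameter recovery on the shared simulated dataset."""

    def test_median_recovery_within_one_millivolt_and_sign_correct(
        self, recovery_dataset
    ):
        for shift, estimates in recovery_dataset["estimates"].items():
            median = float(np.median(estimates))
            assert abs(median - shift) <= 1.0, (shift, median)
            if shift != 0.0:
                assert all(np.sign(e) == np.sign(shift) for e in estimates), shift

    def test_sigma_ordering_matches_amphiphile_directions(self, recovery_dataset):
        # at a fixed potential: phlorizin > control > RH-421 and
        # SDS trans > control > SDS cis
        def mean_sigma_at(curves, v=-55.0):
            return float(
                np.mean([dict(c.points)[v] for c in curves])
            )

        control = mean_sigma_at(recovery_dataset["control_curves"])
        treated = {
            shift: mean_sigma_at(curves)
            for shift, curves in recovery_dataset["treated_curves"].items()
        }
        assert treated[2.8] > control > treated[-3.7]
        assert treated[10.0] > control > treated[-10.0]

    def test_symmetric_perturbation_reproduces_control_activity(
        self, recovery_dataset
    ):
        ratios = []
        for ctrl, sym in zip(
            recovery_dataset["control_curves"],
            recovery_dataset["treated_curves"][0.0],
        ):
            ratios.append(dict(sym.points)[-55.0] / dict(ctrl.points)[-55.0])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestSigmaConcentrationFit:
    def test_model_consistency_log_activity_linear_in_dose(self):
        # Stern-linear regime + exponential activity law, analytic output
        doses = (5.0, 10.0, 15.0, 20.0, 25.0)
        points = []
        for dose in doses:
            _, psi = stern_sds_adsorption(dose * 1e-6)
            sigma = expected_sigma(DEFAULT_MODEL, -40.0, delta_u_mV=abs(psi))
            points.append((dose, sigma))
        fit = fit_sigma_concentration(points, v_applied=-40.0)
        assert fit.r_squared >= 0.99
        assert fit.slope > 0

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_sigma_concentration([(25.0, 1.0), (25.0, 1.1), (25.0, 0.9)], -40.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            fit_sigma_concentration([(5.0, 1.0), (10.0, 0.0), (15.0, 2.0)], -40.0)
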