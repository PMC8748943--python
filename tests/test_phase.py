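"""Phase computation and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomotor import (
    DegenerateDataError,
    InvalidParameterError,
    PhaseAssignment,
    circular_histogram,
    circular_mean,
    event_phase,
    group_rayleigh_on_subject_means,
    per_bin_uniformity_tests,
    rayleigh_test,
    smooth_circular,
)

angles = st.floats(min_value=0.0, max_value=359.999, allow_nan=False)


class TestEventPhase:
    @pytest.mark.parametrize(
        "t_e, prev_r, next_r, expected",
        [
            (1400, 1000, 1800, 180.0),
            (1200, 1000, 1800, 90.0),
            (185.625, 0, 825, 81.0),
        ],
    )
    def test_known_phases(self, t_e, prev_r, next_r, expected):
        assert event_phase(t_e, prev_r, next_r) == pytest.approx(expected)

    def test_event_outside_interval_raises(self):
        with pytest.raises(InvalidParameterError):
            event_phase(900, 1000, 1800)
        with pytest.raises(InvalidParameterError):
            event_phase(1000, 1000, 1800)
        with pytest.raises(InvalidParameterError):
            event_phase(1400, 1800, 1000)

    def test_phase_assignment_invariants(self):
        pa = PhaseAssignment(t_e=1400, prev_r=1000, next_r=1800)
        assert pa.rr == 800
        assert pa.phase == pytest.approx(180.0)
        with pytest.raises(InvalidParameterError):
            PhaseAssignment(t_e=900, prev_r=1000, next_r=1800)

    def test_ms_quantization_shifts_phase_below_half_degree(self, rng):
        """At R-R >= 720 ms a 1-ms rounding error is at most 0.5 degrees."""
        for _ in range(200):
            rr = rng.uniform(720, 2000)
            t = rng.uniform(1e-6, rr - 1e-6)
            exact = t / rr * 360.0
            quantized = np.clip(round(t), 1, round(rr) - 1) / round(rr) * 360.0
            assert abs(exact - quantized) < 0.5 + 360 * abs(rr - round(rr)) / (rr * rr)


class TestCircularMean:
    def test_identical_angles(self):
        assert circular_mean([90.0, 90.0]) == (pytest.approx(90.0), pytest.approx(1.0))

    def test_symmetric_about_zero(self):
        mean, rbar = circular_mean([10.0, 350.0])
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert rbar == pytest.approx(np.cos(np.radians(10.0)))

    def test_balanced_angles_have_undefined_mean(self):
        mean, rbar = circular_mean([0.0, 90.0, 180.0, 270.0])
        assert np.isnan(mean)
        assert rbar == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(InvalidParameterError):
            circular_mean([])


class TestRayleigh:
    def test_identical_phases_maximal_statistic(self):
        res = rayleigh_test([123.0] * 10)
        assert res.rbar == pytest.approx(1.0)
        assert res.z == pytest.approx(10.0)
        assert res.p < 1e-4

    def test_evenly_spaced_phases_are_uniform(self):
        res = rayleigh_test(np.arange(20) * 18.0)
        assert res.z == pytest.approx(0.0, abs=1e-6)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            rayleigh_test([1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(angles, min_size=4, max_size=40))
    def test_z_is_n_times_rbar_squared(self, phases):
        res = rayleigh_test(phases)
        _, rbar = circular_mean(phases)
        assert res.z == pytest.approx(len(phases) * rbar**2, rel=1e-12, abs=1e-12)
        assert 0.0 < res.p <= 1.0

    def test_p_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for n in (5, 12, 40):
            ph = rng.uniform(0, 360, n)
            res = rayleigh_test(ph)
            z_pg, p_pg = pingouin.circular.circ_rayleigh(np.radians(ph))
            assert res.z == pytest.approx(z_pg, rel=1e-9)
            assert res.p == pytest.approx(p_pg, rel=1e-9)


class TestHistogram:
    def test_bin_centers_give_exact_uniformity(self):
        phases = 9.0 + 18.0 * np.arange(20)
        props = circular_histogram(phases).props
        np.testing.assert_array_equal(props, np.full(20, 0.05))

    def test_point_mass_lands_in_one_bin(self):
        props = circular_histogram([100.0] * 7).props
        assert props[5] == 1.0  # bin [90, 108)
        assert props.sum() == 1.0

    def test_edges_are_half_open(self):
        props = circular_histogram([18.0]).props
        assert props[1] == 1.0 and props[0] == 0.0

    def test_empty_raises(self):
        with pytest.raises(InvalidParameterError):
            circular_histogram([])


class TestSmoothing:
    def test_uniform_is_a_fixed_point(self):
        h = circular_histogram(9.0 + 18.0 * np.arange(20))
        np.testing.assert_allclose(smooth_circular(h).props, 0.05)

    def test_delta_spreads_to_circular_neighbors(self):
        h = circular_histogram([5.0] * 3)  # all mass in bin 0
        sm = smooth_circular(h).props
        np.testing.assert_allclose(sm[[19, 0, 1]], 1.0 / 3.0)
        np.testing.assert_allclose(sm[2:19], 0.0)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(angles, min_size=1, max_size=200))
    def test_mass_preserved(self, phases):
        h = circular_histogram(phases)
        assert abs(h.props.sum() - 1.0) < 1e-12
        assert abs(smooth_circular(h).props.sum() - 1.0) < 1e-12

    def test_double_smoothing_rejected(self):
        h = smooth_circular(circular_histogram([5.0]))
        with pytest.raises(InvalidParameterError):
            smooth_circular(h)


class TestPerBinTests:
    def test_exactly_uniform_subjects_have_no_signal(self):
        mat = np.full((10, 20), 0.05)
        out = per_bin_uniformity_tests(mat)
        assert out["zero_variance"].all()
        assert out["t"].isna().all()
        assert not out["sig_unc"].any()

    def test_elevated_bin_is_flagged_and_bonferroni_is_exact(self, rng):
        mat = rng.normal(0.05, 0.005, size=(25, 20))
        mat[:, 4] += 0.03  # elevate the bin centered on 81 degrees
        mat = mat / mat.sum(axis=1, keepdims=True)
        out = per_bin_uniformity_tests(mat)
        assert bool(out.loc[4, "sig_unc"])
        assert out.loc[4, "mean_prop"] > 0.05
        np.testing.assert_allclose(
            out["p_bonf"], np.minimum(1.0, 20 * out["p_unc"]), rtol=1e-12
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidParameterError):
            per_bin_uniformity_tests(np.full((2, 20), 0.05))


class TestGroupRayleigh:
    def test_concentrated_subject_means(self):
        res = group_rayleigh_on_subject_means(np.full(25, 210.0))
        assert res.p < 1e-6

    def test_evenly_spread_subject_means(self):
        res = group_rayleigh_on_subject_means(np.arange(20) * 18.0)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_nan_means_excluded_with_warning(self):
        means = np.array([10.0, 20.0, 30.0, 40.0, np.nan])
        with pytest.warns(UserWarning, match="undefined"):
            res = group_rayleigh_on_subject_means(means)
        assert res.n == 4

    def test_too_few_usable_means(self):
        with pytest.raises(DegenerateDataError):
            group_rayleigh_on_subject_means(np.array([10.0, 20.0, np.nan, np.nan]))

    def test_uniform_subject_means_are_calibrated(self, rng):
        """Type-I error of the group Rayleigh test stays near alpha."""
        rej = sum(
            rayleigh_test(rng.uniform(0, 360, 25)).p < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.07


class TestVonMisesRecovery:
    def test_circular_mean_recovers_preferred_phase(self, rng):
        """kappa=1, n=200: the error of the circular mean follows its
        asymptotic law, sd = 1/sqrt(n*kappa*A(kappa)) = 6.06 degrees, so
        ~90% of subjects land within 10 degrees of mu."""
        mu = 81.0
        errs = []
        for _ in range(500):
            ph = np.degrees(rng.vonmises(np.radians(mu), 1.0, 200)) % 360.0
            mean, _ = circular_mean(ph)
            errs.append(abs((mean - mu + 180.0) % 360.0 - 180.0))
        errs = np.asarray(errs)
        # P(|err| <= 10 deg) = P(|Z| <= 10/6.06) = 0.901; allow MC noise
        assert 0.86 <= np.mean(errs <= 10.0) <= 0.95
        assert np.median(errs) <= 6.0  # median of |N(0, 6.06)| = 4.1 deg
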