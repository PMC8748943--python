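"""Generator tests: ground truth, determinism, and injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiomotor import (
    InvalidParameterError,
    SimulationConfig,
    assign_phases,
    circular_histogram,
    circular_mean,
    generate_dyad_dataset,
    generate_events,
    generate_rr_train,
)


class TestRRTrain:
    def test_zero_variance_is_a_metronome(self):
        train = generate_rr_train(3, mean_rr=800, sd_rr=0)
        assert train.times.tolist() == [0, 800, 1600]
        train = generate_rr_train(2, mean_rr=825, sd_rr=0)
        assert np.diff(train.times).tolist() == [825]

    def test_sample_mean_interval_near_target(self):
        train = generate_rr_train(2000, mean_rr=825, sd_rr=40, seed=1)
        mean = np.diff(train.times).mean()
        assert 822 <= mean <= 828  # 3*sd/sqrt(n) band around 825

    def test_intervals_respect_truncation_bounds(self):
        train = generate_rr_train(5000, mean_rr=825, sd_rr=40, seed=2)
        rr = np.diff(train.times)
        assert rr.min() >= 300 and rr.max() <= 2000
        assert np.all(rr > 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_beats=1),
            dict(n_beats=10, mean_rr=-5),
            dict(n_beats=10, sd_rr=-1),
            dict(n_beats=10, mean_rr=400, sd_rr=150),  # mean <= 4*sd
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_rr_train(**kwargs)


class TestEventGeneration:
    def test_kappa_zero_von_mises_is_uniform(self, long_train):
        """von Mises with zero concentration must be indistinguishable from uniform."""
        cfg = SimulationConfig(coupling_mode="von_mises", mu=90.0, kappa=0.0,
                               movement_time_mean=300, movement_time_within_sd=120)
        train = generate_rr_train(3000, seed=5)
        _, truth = generate_events(train, 5000, cfg, seed=0)
        stat = sps.kstest(truth.true_phases / 360.0, "uniform")
        assert stat.pvalue > 0.01

    def test_von_mises_mean_phase_recovered(self, long_train):
        cfg = SimulationConfig(coupling_mode="von_mises", mu=180.0, kappa=50.0)
        _, truth = generate_events(long_train, 500, cfg, seed=4)
        mean, rbar = circular_mean(truth.true_phases)
        assert abs(mean - 180.0) <= 5.0
        assert rbar > 0.9

    def test_suppression_factor_one_removes_nothing(self, long_train):
        cfg = SimulationConfig(coupling_mode="time_suppression", suppression_factor=1.0)
        t, _ = generate_events(long_train, 300, cfg, seed=8)
        assert t.size == 300

    def test_full_suppression_empties_the_window(self, long_train):
        cfg = SimulationConfig(
            coupling_mode="time_suppression", suppression_factor=0.0,
            suppression_center=0.0, suppression_halfwidth=100.0,
        )
        t, _ = generate_events(long_train, 400, cfg, seed=9)
        rt = long_train.times
        idx = np.searchsorted(rt, t, side="right") - 1
        lat_prev = t - rt[idx]
        lat_next = t - rt[idx + 1]
        lam = np.where(lat_prev <= -lat_next, lat_prev, lat_next)
        assert t.size < 400  # thinning removed something
        assert np.all(np.abs(lam) > 100)

    def test_events_strictly_inside_train_span(self, long_train):
        for mode in ("uniform", "von_mises", "time_suppression"):
            cfg = SimulationConfig(coupling_mode=mode, kappa=2.0)
            t, _ = generate_events(long_train, 200, cfg, seed=10)
            assert np.all(np.diff(t) > 0)
            assert t.min() > long_train.times[0]
            assert t.max() < long_train.times[-1]

    def test_uniform_mode_bins_are_flat(self):
        """Over 1e5 uniform events every 18-degree bin holds 0.05 +/- 0.005."""
        cfg = SimulationConfig(coupling_mode="uniform", movement_time_mean=1250)
        train = generate_rr_train(160000, 825, 40, seed=2)
        _, truth = generate_events(train, 100000, cfg, seed=3)
        props = circular_histogram(truth.true_phases).props
        assert np.all(np.abs(props - 0.05) < 0.005)

    def test_ground_truth_phases_match_phase_module_exactly(self, long_train):
        cfg = SimulationConfig(coupling_mode="von_mises", mu=81.0, kappa=0.5)
        t, truth = generate_events(long_train, 250, cfg, seed=12)
        recomputed = assign_phases(t, long_train)
        assert len(recomputed) == t.size
        np.testing.assert_array_equal(recomputed["event_time_ms"].to_numpy(), t)
        np.testing.assert_allclose(
            recomputed["phase_deg"].to_numpy(), truth.true_phases, rtol=0, atol=0
        )

    def test_empty_train_and_bad_kappa_raise(self, long_train):
        from cardiomotor import EmptyTrainError, RPeakTrain

        with pytest.raises(EmptyTrainError):
            generate_events(RPeakTrain(np.array([1000])), 10, SimulationConfig())
        with pytest.raises(InvalidParameterError):
            SimulationConfig(coupling_mode="von_mises", kappa=-1.0)


class TestDyadDataset:
    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_dyads=2, coupling_mode="von_mises", mu=45, kappa=1.0)
        a = generate_dyad_dataset(cfg, seed=21)
        b = generate_dyad_dataset(cfg, seed=21)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert a.events.to_csv(index=False) == b.events.to_csv(index=False)
        for s in a.rpeaks:
            np.testing.assert_array_equal(a.rpeaks[s].times, b.rpeaks[s].times)

    def test_counterbalanced_turn_taking(self):
        for blocks in (2, 4):
            ds = generate_dyad_dataset(SimulationConfig(n_dyads=1, blocks_per_dyad=blocks), seed=3)
            ex = ds.events[ds.events["role"] == "execution"]
            per_subject = ex.groupby("subject_id")["block"].nunique()
            assert per_subject.tolist() == [blocks // 2, blocks // 2]
            # executor alternates: no subject executes two consecutive blocks
            executor_by_block = ex.groupby("block")["subject_id"].first()
            assert all(
                executor_by_block[b] != executor_by_block[b + 1]
                for b in range(blocks - 1)
            )

    def test_every_event_inside_both_subjects_trains(self, small_dataset):
        ds = small_dataset
        for s, g in ds.events.groupby("subject_id"):
            t = g["event_time_ms"].to_numpy()
            assert t.min() > ds.rpeaks[s].times[0]
            assert t.max() < ds.rpeaks[s].times[-1]

    def test_observation_mirrors_execution_times(self, small_dataset):
        ev = small_dataset.events
        for (dyad, block, trial), g in ev.groupby(["dyad_id", "block", "trial"]):
            roles = g.groupby("role")["event_time_ms"].apply(sorted)
            assert roles["execution"] == roles["observation"]

    def test_perfect_movement_correlation_means_equal_speeds(self):
        cfg = SimulationConfig(n_dyads=6, movement_time_corr=1.0)
        ds = generate_dyad_dataset(cfg, seed=17)
        wide = ds.movement_times.pivot(
            index="dyad_id", columns="subject_id", values="true_mean_gap_ms"
        )
        per_dyad = ds.movement_times.groupby("dyad_id")["true_mean_gap_ms"].agg(["min", "max"])
        # SVD-based sampling of the singular covariance leaves ~1e-8 asymmetry
        np.testing.assert_allclose(per_dyad["min"], per_dyad["max"], rtol=1e-6)

    def test_odd_blocks_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(blocks_per_dyad=3)
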