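"""Kinetic Monte-Carlo simulator: physics, determinism, calibration."""

import numpy as np
import pytest

import rejmech as rm
from rejmech.constructs import ConstructSpec, KineticParams, Segment
from rejmech.simulate import (
    ConfigurationError,
    SimulationConfig,
    _modal_force,
    calibrate_bell,
)


def dataset_bytes(directory):
    return {
        p.name: p.read_bytes()
        for p in sorted(directory.iterdir()) if p.is_file()
    }


class TestSimulateTrace:
    def test_ground_truth_event_structure(self, i27_batch, i27_construct):
        for trace, events in i27_batch:
            labels = [e.label for e in events]
            assert labels.count("I27") == 5
            assert labels[-1] == "detach"
            assert events[-1].true_force > 400
            # contour release bookkeeping: every I27 frees its full gain
            for e in events[:-1]:
                assert e.released_gain == pytest.approx(28.085, abs=1e-9)

    def test_extension_monotone_and_zeroed(self, i27_batch):
        for trace, _ in i27_batch:
            assert trace.extension[0] == 0.0
            assert np.all(np.diff(trace.extension) >= 0)

    def test_seed_reproducibility(self, i27_construct, default_config):
        t1, e1 = rm.simulate_trace(i27_construct, config=default_config, rng=5)
        t2, e2 = rm.simulate_trace(i27_construct, config=default_config, rng=5)
        np.testing.assert_array_equal(t1.force, t2.force)
        assert e1 == e2

    def test_zero_folded_construct_is_monotone_rise(self, default_config):
        coil = ConstructSpec("bare-coil", (Segment("c", "coil", 300, False),))
        cfg = SimulationConfig(force_noise_sd=0.0, artifact_amplitude=0.0)
        trace, events = rm.simulate_trace(coil, kinetics={}, config=cfg, rng=0)
        assert [e.label for e in events] == ["detach"]
        upto = np.argmax(trace.force)
        assert np.all(np.diff(trace.force[: upto + 1]) >= 0)

    def test_early_detachment_mode(self, i27_construct):
        cfg = SimulationConfig(early_detachment=True)
        _, events = rm.simulate_trace(i27_construct, config=cfg, rng=3)
        assert events[-1].label == "detach"
        assert events[-1].true_force < 200

    def test_under_resolved_grid_rejected(self, i27_construct):
        cfg = SimulationConfig(grid_step=50.0)
        with pytest.raises(ConfigurationError, match="grid_step"):
            rm.simulate_trace(i27_construct, config=cfg, rng=0)


class TestNoiseFreeFullLoop:
    def test_pipeline_recovers_every_event(self, i27_construct):
        # with zero noise and no artifact the analysis is an identity map
        cfg = SimulationConfig(force_noise_sd=0.0, artifact_amplitude=0.0)
        for seed in range(10):
            trace, events = rm.simulate_trace(i27_construct, config=cfg, rng=seed)
            a = rm.analyze_trace(trace)
            assert len(a.peaks) == len(events)
            for peak, truth in zip(a.unfolding_peaks, events[:-1]):
                if peak.delta_Lc is not None:
                    assert peak.delta_Lc == pytest.approx(28.085, rel=0.01)


class TestSimulateDataset:
    def test_byte_identical_reruns(self, tmp_path, i27_construct, default_config):
        d1 = rm.simulate_dataset(i27_construct, 4, tmp_path / "a",
                                 config=default_config, master_seed=9)
        d2 = rm.simulate_dataset(i27_construct, 4, tmp_path / "b",
                                 config=default_config, master_seed=9)
        assert dataset_bytes(d1) == dataset_bytes(d2)

    def test_different_seeds_differ(self, tmp_path, i27_construct, default_config):
        d1 = rm.simulate_dataset(i27_construct, 2, tmp_path / "a",
                                 config=default_config, master_seed=1)
        d2 = rm.simulate_dataset(i27_construct, 2, tmp_path / "b",
                                 config=default_config, master_seed=2)
        assert dataset_bytes(d1) != dataset_bytes(d2)

    def test_round_trip_and_truth_table(self, tmp_path, i27_construct,
                                        default_config):
        out = rm.simulate_dataset(i27_construct, 3, tmp_path / "ds",
                                  config=default_config, master_seed=4)
        traces, truth, manifest = rm.load_dataset(out)
        assert len(traces) == 3
        assert manifest["construct"] == i27_construct.name
        assert set(truth["trace_id"]) == set(manifest["trace_ids"])
        assert (truth[truth.label == "I27"].groupby("trace_id").size() == 5).all()

    def test_zero_traces_rejected(self, tmp_path, i27_construct):
        with pytest.raises(ValueError):
            rm.simulate_dataset(i27_construct, 0, tmp_path / "x")


class TestBellPhysics:
    def test_force_increases_with_pulling_speed(self, i27_construct):
        # Bell-Evans monotonicity over ~500 events per speed
        means = []
        for speed in (0.5, 5.0):
            cfg = SimulationConfig(pulling_speed=speed)
            forces = []
            for i in range(100):
                _, ev = rm.simulate_trace(i27_construct, config=cfg,
                                          rng=np.random.default_rng((int(speed * 10), i)))
                forces += [e.true_force for e in ev if e.label == "I27"]
            assert len(forces) == 500
            means.append(np.mean(forces))
        assert means[1] > means[0]

    def test_contour_length_non_decreasing(self, i27_batch, i27_construct):
        for _, events in i27_batch:
            gains = [e.released_gain for e in events]
            assert all(g >= 0 for g in gains)
            unfolded_total = sum(e.released_gain for e in events if e.label != "detach")
            final = rm.chain_contour_length(
                i27_construct, state=[False] * len(i27_construct.segments))
            initial = rm.chain_contour_length(i27_construct)
            assert unfolded_total == pytest.approx(final - initial, abs=1e-9)


class TestCalibrateBell:
    def test_modal_target_reached(self, default_config):
        params = calibrate_bell(200.0, default_config,
                                contour_length_at_event=60.0, target_sd=30.0,
                                statistic="modal", seed=2)
        single = ConstructSpec("one", (
            Segment("sp", "coil", 152, False),
            Segment("I27-1", "I27", 89, True, "I27")))
        forces = []
        for i in range(200):
            _, ev = rm.simulate_trace(single, kinetics={"I27": params},
                                      config=default_config,
                                      rng=np.random.default_rng((7, i)))
            forces += [e.true_force for e in ev if e.label == "I27"]
        assert _modal_force(np.asarray(forces)) == pytest.approx(200.0, rel=0.10)

    def test_mean_target_reached(self, default_config):
        params = calibrate_bell(63.0, default_config,
                                contour_length_at_event=80.0, target_sd=37.0,
                                statistic="mean", seed=2)
        from rejmech.simulate import _single_domain_forces
        rng = np.random.default_rng(0)
        forces = _single_domain_forces(2000, params.k0, params.delta_x, 80.0,
                                       default_config, rng)
        assert np.mean(forces) == pytest.approx(63.0, rel=0.10)

    def test_unreachable_sd_warns(self, default_config):
        with pytest.warns(UserWarning, match="SD"):
            calibrate_bell(150.0, default_config, target_sd=200.0, seed=0,
                           n_iter=2, n_events=200)

    def test_sub_resolution_target_rejected(self, default_config):
        with pytest.raises(ValueError):
            calibrate_bell(0.0, default_config)
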