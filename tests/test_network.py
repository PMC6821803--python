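"""Network-burst detection and the well-level metric vector."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import netburst as nb
from helpers import poisson_train
from netburst.network import spikes_in_network_bursts


def make_well(trains_spec, duration=1200.0, well_id="W01"):
    trains = [
        nb.SpikeTrain(eid, well_id, times, duration) for eid, times in trains_spec
    ]
    return nb.WellRecording(well_id, trains)


def synchronous_bursts(channels, onsets, width=0.5):
    """Channel-burst dict with one burst per onset on each listed channel."""
    return {
        ch: [nb.Burst(ch, on, on + width, 10) for on in onsets] for ch in channels
    }


class TestActiveElectrodes:
    def test_boundary_rate_is_active_inclusive(self):
        well = make_well([("E01", np.linspace(5, 1195, 120))])  # 0.1 Hz
        assert nb.active_electrodes(well, 0.1) == {"E01"}

    def test_empty_train_is_inactive(self):
        well = make_well([("E01", np.array([])), ("E02", np.linspace(1, 1100, 500))])
        assert nb.active_electrodes(well) == {"E02"}

    def test_matches_brute_force_rate_filter(self, rng):
        spec = [
            (f"E{i:02d}", poisson_train(rng, rng.uniform(0.01, 1.0), 600.0))
            for i in range(1, 13)
        ]
        well = make_well(spec, duration=600.0)
        brute = {eid for eid, t in spec if len(t) / 600.0 >= 0.1}
        assert nb.active_electrodes(well) == brute


class TestMeanFiringRate:
    def test_simple_average(self):
        well = make_well(
            [
                ("E01", np.linspace(0.001, 1199, 1200)),  # 1 Hz
                ("E02", np.linspace(0.001, 1199.5, 2400)),  # 2 Hz
                ("E03", np.linspace(0.001, 1199.7, 3600)),  # 3 Hz
            ]
        )
        active = nb.active_electrodes(well)
        assert nb.mean_firing_rate(well, active) == pytest.approx(2.0)

    def test_single_active_channel_is_identity(self):
        well = make_well([("E01", np.linspace(1, 1100, 600))])
        assert nb.mean_firing_rate(well, {"E01"}) == pytest.approx(600 / 1200)

    def test_no_active_electrodes_gives_nan_sentinel(self):
        well = make_well([("E01", np.array([]))])
        with pytest.warns(UserWarning):
            assert np.isnan(nb.mean_firing_rate(well, set()))


class TestDetectNetworkBursts:
    ACTIVE = {f"E{i:02d}" for i in range(1, 11)}  # 10 active channels

    def test_nine_of_ten_channels_is_a_network_burst(self):
        cb = synchronous_bursts(sorted(self.ACTIVE)[:9], onsets=[10.0])
        nbs = nb.detect_network_bursts(cb, self.ACTIVE)
        assert len(nbs) == 1
        assert len(nbs[0].channels) == 9

    def test_eight_of_ten_channels_is_not(self):
        cb = synchronous_bursts(sorted(self.ACTIVE)[:8], onsets=[10.0])
        assert nb.detect_network_bursts(cb, self.ACTIVE) == []

    def test_extent_and_spike_count_aggregate_members(self):
        cb = {
            ch: [nb.Burst(ch, 10.0 + i * 0.01, 10.4 + i * 0.01, 7)]
            for i, ch in enumerate(sorted(self.ACTIVE))
        }
        nbs = nb.detect_network_bursts(cb, self.ACTIVE)
        assert len(nbs) == 1
        event = nbs[0]
        assert event.start == pytest.approx(10.0)
        assert event.end == pytest.approx(10.49)
        assert event.n_spikes == 70

    def test_gap_beyond_merge_gap_splits_events(self):
        cb = {
            ch: [nb.Burst(ch, 10.0, 10.4, 7), nb.Burst(ch, 11.0, 11.4, 7)]
            for ch in self.ACTIVE
        }
        nbs = nb.detect_network_bursts(cb, self.ACTIVE, merge_gap=0.1)
        assert len(nbs) == 2

    def test_count_non_increasing_in_participation(self):
        rng = np.random.default_rng(0)
        cb = {
            ch: [nb.Burst(ch, on, on + 0.3, 6) for on in np.arange(5, 100, 5.0)
                 if rng.random() < 0.85]
            for ch in self.ACTIVE
        }
        counts = [
            len(nb.detect_network_bursts(cb, self.ACTIVE, participation=p))
            for p in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_fewer_than_two_active_channels_warns_empty(self):
        with pytest.warns(UserWarning):
            assert nb.detect_network_bursts({}, {"E01"}) == []

    def test_ground_truth_recovery_on_clean_simulation(self):
        cfg = replace(nb.control_preset(seed=21), background_rate=0.0, duration=600.0)
        well, truth = nb.simulate_well(cfg)
        metrics = nb.summarize_well(well)
        assert metrics.n_network_bursts == truth.n_bursts
        # recompute NB onsets through the chain for timing comparison
        active = nb.active_electrodes(well)
        cb = {
            t.electrode_id: nb.detect_bursts_logisi(t)[0]
            for t in well.trains if t.electrode_id in active
        }
        nbs = sorted(nb.detect_network_bursts(cb, active), key=lambda e: e.start)
        np.testing.assert_allclose(
            [e.start for e in nbs], truth.nb_onsets, atol=0.05
        )


class TestNetworkBurstStats:
    def test_forty_bursts_in_twenty_minutes_is_two_per_minute(self):
        nbs = [
            nb.NetworkBurst(i * 30.0, i * 30.0 + 1.0, frozenset({"E01", "E02"}), 10)
            for i in range(40)
        ]
        stats = nb.network_burst_stats(nbs, duration=1200.0)
        assert stats["nb_rate"] == pytest.approx(2.0)

    def test_nibi_is_end_to_next_start(self):
        nbs = [
            nb.NetworkBurst(0.0, 1.0, frozenset({"E01", "E02"}), 5),
            nb.NetworkBurst(10.0, 11.0, frozenset({"E01", "E02"}), 5),
            nb.NetworkBurst(20.0, 21.0, frozenset({"E01", "E02"}), 5),
        ]
        stats = nb.network_burst_stats(nbs, duration=60.0)
        np.testing.assert_allclose(stats["nibis"], [9.0, 9.0])
        assert stats["mean_nibi"] == pytest.approx(9.0)

    def test_histogram_counts_conserve(self):
        rng = np.random.default_rng(1)
        onsets = np.cumsum(rng.uniform(2, 30, 50))
        nbs = [
            nb.NetworkBurst(o, o + rng.uniform(0.2, 3.0), frozenset({"a", "b"}), 5)
            for o in onsets
        ]
        stats = nb.network_burst_stats(nbs, duration=float(onsets[-1] + 10))
        assert stats["nbd_hist"][0].sum() == len(nbs)
        assert stats["nibi_hist"][0].sum() == len(nbs) - 1

    def test_single_burst_has_undefined_nibi(self):
        nbs = [nb.NetworkBurst(1.0, 2.0, frozenset({"a", "b"}), 5)]
        stats = nb.network_burst_stats(nbs, duration=60.0)
        assert stats["nibis"].size == 0 and np.isnan(stats["mean_nibi"])


class TestCvNibi:
    def test_periodic_is_zero(self):
        assert nb.cv_nibi([5.0, 5.0, 5.0, 5.0]) == 0.0
        assert nb.cv_nibi([7.0, 7.0]) == 0.0

    def test_gamma_shape_four_has_cv_half(self, rng):
        nibis = rng.gamma(4.0, 2.0, size=500)  # analytic CV = 1/sqrt(4)
        assert nb.cv_nibi(nibis) == pytest.approx(0.5, rel=0.10)

    def test_single_interval_is_undefined(self):
        assert np.isnan(nb.cv_nibi([4.0]))


class TestPctSpikesOutside:
    def test_all_inside_is_zero_percent(self):
        well = make_well([("E01", np.linspace(10.01, 10.99, 50)),
                          ("E02", np.linspace(10.02, 10.98, 50))], duration=60.0)
        nbs = [nb.NetworkBurst(10.0, 11.0, frozenset({"E01", "E02"}), 100)]
        assert nb.pct_spikes_outside(well, {"E01", "E02"}, nbs) == 0.0

    def test_no_network_bursts_is_hundred_percent(self):
        well = make_well([("E01", np.linspace(1, 50, 100))], duration=60.0)
        assert nb.pct_spikes_outside(well, {"E01"}, []) == 100.0

    def test_matches_ground_truth_background_fraction(self):
        cfg = nb.control_preset(seed=33)  # ~30% of spikes are background
        well, truth = nb.simulate_well(cfg)
        metrics = nb.summarize_well(well)
        expected = 100.0 * truth.background_fraction()
        assert abs(metrics.pct_outside - expected) < 5.0

    def test_conservation_inside_plus_outside_equals_total(self):
        well, _ = nb.simulate_well(nb.control_preset(seed=44))
        active = nb.active_electrodes(well)
        cb = {
            t.electrode_id: nb.detect_bursts_logisi(t)[0]
            for t in well.trains if t.electrode_id in active
        }
        nbs = nb.detect_network_bursts(cb, active)
        total = inside = outside = 0
        for train in well.trains:
            if train.electrode_id not in active:
                continue
            total += train.n_spikes
            inside += spikes_in_network_bursts(train, nbs)
            # independent per-spike scan
            for t in train.spike_times:
                if not any(e.start <= t <= e.end for e in nbs):
                    outside += 1
        assert inside + outside == total


class TestSummarizeWell:
    def test_control_preset_gives_finite_metrics(self):
        well, _ = nb.simulate_well(nb.control_preset(seed=2))
        m = nb.summarize_well(well)
        for f in ("mfr", "nb_rate", "mean_nbd", "mean_nibi", "cv_nibi", "pct_outside"):
            assert np.isfinite(getattr(m, f))
        assert m.nb_rate > 0 and m.n_active == 12

    def test_deterministic_on_identical_input(self):
        well, _ = nb.simulate_well(nb.control_preset(seed=3))
        assert nb.summarize_well(well) == nb.summarize_well(well)

    def test_group_ordering_matches_phenotype(self):
        pc, _ = nb.simulate_plate(nb.control_preset(seed=5), 10, group_label="control")
        pk, _ = nb.simulate_plate(nb.ks_preset(seed=6), 10, group_label="ks")
        c = nb.summarize_plate(pc).mean(numeric_only=True)
        k = nb.summarize_plate(pk).mean(numeric_only=True)
        assert k.nb_rate < c.nb_rate
        assert k.mean_nbd > c.mean_nbd
        assert k.cv_nibi > c.cv_nibi
        assert k.pct_outside < c.pct_outside

    def test_parameter_recovery_within_15pct(self):
        cfg = nb.SimulationConfig(mean_nibi=20.0, cv_nibi=0.5, mean_nbd=2.0, seed=10)
        plate, _ = nb.simulate_plate(cfg, 10)
        df = nb.summarize_plate(plate)
        assert df.mean_nibi.mean() == pytest.approx(20.0, rel=0.15)
        assert df.cv_nibi.mean() == pytest.approx(0.5, rel=0.15)
        assert df.mean_nbd.mean() == pytest.approx(2.0, rel=0.15)
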