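import numpy as np
import pytest

from ei_netsim.dynamics import SpikeTrainSet
from ei_netsim.mea import (
    assign_electrodes,
    avalanche_statistics,
    detect_bursts,
    electrode_metrics,
    electrode_train,
    mean_bursting_rate,
    mean_firing_rate,
    percent_change,
)

from _oracles import brute_force_bursts


def _set(trains, duration=10.0, n_exc=None, n_inh=0):
    n_exc = (max(trains) + 1) if n_exc is None else n_exc
    return SpikeTrainSet(
        trains={k: np.asarray(v, dtype=float) for k, v in trains.items()},
        duration=duration,
        n_exc=n_exc,
        n_inh=n_inh,
    )


class TestElectrodeAssignment:
    def test_bounds_and_disjointness(self, rng):
        emap = assign_electrodes(1000, n_electrodes=59, group_min=10,
                                 group_max=15, rng=rng)
        sizes = [len(m) for m in emap.members.values()]
        assert len(emap.members) == 59
        assert all(10 <= s <= 15 for s in sizes)
        assert 590 <= sum(sizes) <= 885
        emap.validate(1000)  # raises on overlap

    def test_same_seed_identical_map(self):
        a = assign_electrodes(200, 13, rng=np.random.default_rng(5))
        b = assign_electrodes(200, 13, rng=np.random.default_rng(5))
        assert all(np.array_equal(a.members[k], b.members[k]) for k in a.members)

    def test_single_neuron_groups(self, rng):
        emap = assign_electrodes(59, n_electrodes=59, group_min=1, group_max=1,
                                 rng=rng)
        assert all(len(m) == 1 for m in emap.members.values())

    def test_insufficient_neurons(self, rng):
        with pytest.raises(ValueError):
            assign_electrodes(100, n_electrodes=59, group_min=10, group_max=15,
                              rng=rng)


class TestElectrodeTrain:
    def test_merge_sorted(self):
        s = _set({0: [0.1, 0.3], 1: [0.2]})
        assert np.allclose(electrode_train(s, [0, 1]), [0.1, 0.2, 0.3])

    def test_single_member_identity(self):
        s = _set({0: [0.5, 0.7]})
        assert np.allclose(electrode_train(s, [0]), [0.5, 0.7])

    def test_duplicate_timestamps_kept(self):
        s = _set({0: [0.2], 1: [0.2]})
        assert len(electrode_train(s, [0, 1])) == 2

    def test_unknown_member(self):
        s = _set({0: [0.1]})
        with pytest.raises(KeyError):
            electrode_train(s, [99])

    def test_conservation_and_additivity(self, rng):
        trains = {i: np.sort(rng.uniform(0, 10, rng.integers(0, 50)))
                  for i in range(30)}
        s = _set(trains)
        members = list(range(30))
        merged = electrode_train(s, members)
        assert len(merged) == sum(len(t) for t in trains.values())
        assert mean_firing_rate(merged, 10.0) == pytest.approx(
            sum(mean_firing_rate(t, 10.0) for t in trains.values())
        )


class TestRates:
    def test_mfr_definition(self):
        assert mean_firing_rate(np.zeros(900), 60.0) == 15.0
        assert mean_firing_rate(np.empty(0), 60.0) == 0.0

    def test_mfr_poisson_recovery(self):
        from ei_netsim.synth import gen_poisson_train
        from _oracles import poisson_count_bounds

        train = gen_poisson_train(5.0, 200.0, seed=3)
        lo, hi = poisson_count_bounds(5.0, 200.0)
        assert lo <= len(train) <= hi
        assert mean_firing_rate(train, 200.0) == pytest.approx(
            5.0, abs=3 * np.sqrt(5.0 / 200.0)
        )

    def test_mbr_definition(self):
        assert mean_bursting_rate(10, 300.0) == 2.0
        assert mean_bursting_rate(0, 300.0) == 0.0

    def test_adding_spikes_never_decreases_mfr(self, rng):
        t = np.sort(rng.uniform(0, 10, 50))
        more = np.sort(np.concatenate([t, rng.uniform(0, 10, 10)]))
        assert mean_firing_rate(more, 10.0) >= mean_firing_rate(t, 10.0)


class TestBurstDetection:
    def test_constructed_two_bursts(self):
        train = np.array([0, 0.01, 0.02, 0.03, 0.04, 1.0, 1.01, 1.02, 1.03, 1.04])
        bl = detect_bursts(train, max_isi_ms=100.0, min_spikes=5)
        assert len(bl) == 2
        assert bl.bursts[0].start == 0 and bl.bursts[0].n_spikes == 5

    def test_no_bursts_when_all_isis_long(self):
        train = np.arange(0, 10, 0.5)  # 500 ms gaps
        assert len(detect_bursts(train, 100.0, 5)) == 0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([0.2, 0.1]), 100.0, 5)

    def test_matches_brute_force_on_random_trains(self, rng):
        """Greedy detector == exhaustive maximal-run enumeration, exactly."""
        for _ in range(1000):
            n = int(rng.integers(0, 25))
            train = np.sort(rng.uniform(0, 2.0, n))
            max_isi = float(rng.choice([20.0, 50.0, 100.0, 200.0]))
            min_spikes = int(rng.integers(2, 6))
            bl = detect_bursts(train, max_isi, min_spikes)
            got = [(b.start, b.end, b.n_spikes) for b in bl.bursts]
            assert got == brute_force_bursts(train, max_isi, min_spikes)

    def test_merging_disjoint_bursty_trains_adds_bursts(self):
        a = np.array([0, 0.01, 0.02, 0.03, 0.04])
        b = a + 5.0
        na = len(detect_bursts(a, 100.0, 5))
        nb = len(detect_bursts(b, 100.0, 5))
        merged = np.sort(np.concatenate([a, b]))
        assert len(detect_bursts(merged, 100.0, 5)) == na + nb


class TestPercentChange:
    def test_examples(self):
        assert percent_change(10, 17) == (70.0, True)
        assert percent_change(10, 10) == (0.0, True)

    def test_zero_baseline_fallback(self):
        value, is_pct = percent_change(0, 3)
        assert value == 3 and not is_pct


class TestAvalanches:
    def test_single_spike_single_avalanche(self):
        s = _set({0: [1.0]}, duration=10.0)
        st = avalanche_statistics(s, bin_ms=5.0)
        assert list(st.sizes) == [1]
        assert np.isnan(st.branching_ratio)  # no within-avalanche transition

    def test_separated_spikes_two_avalanches(self):
        s = _set({0: [1.0, 1.02]}, duration=10.0)  # 20 ms apart, 5 ms bins
        st = avalanche_statistics(s, bin_ms=5.0)
        assert len(st.sizes) == 2

    def test_branching_ratio_hand_computed(self):
        # bins: [3 spikes][6 spikes][empty]... ratio = 6/3 = 2
        s = _set({0: [0.001, 0.002, 0.003, 0.006, 0.0065, 0.007, 0.0075,
                      0.008, 0.009]}, duration=1.0)
        st = avalanche_statistics(s, bin_ms=5.0)
        assert st.branching_ratio == pytest.approx(2.0)
        assert list(st.sizes) == [9]

    def test_empty_set_flagged(self):
        s = _set({}, duration=10.0, n_exc=5)
        st = avalanche_statistics(s, bin_ms=5.0)
        assert len(st.sizes) == 0 and np.isnan(st.branching_ratio)

    def test_short_recording_rejected(self):
        s = _set({0: [0.01]}, duration=0.2)
        with pytest.raises(ValueError):
            avalanche_statistics(s, bin_ms=5.0)


class TestMetricsTable:
    def test_table_consistency(self, rng):
        trains = {i: np.sort(rng.uniform(0, 10, rng.integers(5, 40)))
                  for i in range(40)}
        s = _set(trains)
        emap = assign_electrodes(40, n_electrodes=4, group_min=5, group_max=10,
                                 rng=rng)
        df = electrode_metrics(s, emap)
        assert (df["mfr_hz"] >= 0).all() and (df["mbr_per_min"] >= 0).all()
        total_member_spikes = sum(
            len(trains[m]) for ms in emap.members.values() for m in ms
        )
        assert df["n_spikes"].sum() == total_member_spikes
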