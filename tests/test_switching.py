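"""Non-ideal relay semantics, residence statistics, and escape times."""

import numpy as np
import pytest

from rcswitching import (RelayThresholds, TransitionSequence,
                         closed_loop_projection, collect_switchings,
                         escape_time, escape_time_sweep, log_binned_density,
                         relay_transitions, residence_durations,
                         residence_histogram)
from rcswitching.switching import _Relay, winding_counts

THR = RelayThresholds()  # alpha = -2, beta = 2


class TestRelayTransitions:
    def test_in_band_dip_is_ignored(self):
        # a single mid-band threshold would miscount the dip to 0
        ts = relay_transitions([3.0, 0.0, 3.0], [0.0, 1.0, 2.0], THR)
        assert ts.initial_state == "B"
        assert len(ts) == 0

    def test_full_swings_alternate(self):
        ts = relay_transitions([3.0, -3.0, 3.0, -3.0], [0.0, 1.0, 2.0, 3.0],
                               THR)
        assert ts.initial_state == "B"
        assert ts.entries == [(1.0, "A"), (2.0, "B"), (3.0, "A")]

    def test_never_crossing_stays_undetermined(self):
        ts = relay_transitions(np.zeros(50), np.arange(50.0), THR)
        assert ts.initial_state == "undetermined"
        assert len(ts) == 0

    def test_exact_threshold_hits_do_not_trigger(self):
        ts = relay_transitions([3.0, -2.0, 2.0, -2.0], np.arange(4.0), THR)
        assert len(ts) == 0

    def test_custom_state_labels(self):
        ts = relay_transitions([3.0, -3.0], [0.0, 1.0], THR,
                               low_state="B", high_state="A")
        assert ts.initial_state == "A"
        assert ts.entries == [(1.0, "B")]

    def test_causality_under_truncation(self, rng):
        for _ in range(25):
            x = rng.uniform(-5, 5, size=60)
            t = np.arange(60.0)
            full = relay_transitions(x, t, THR)
            k = rng.integers(5, 60)
            head = relay_transitions(x[:k], t[:k], THR)
            early = [e for e in full.entries if e[0] <= t[k - 1]]
            assert head.entries == early

    def test_incremental_feed_matches_batch(self, rng):
        x = rng.uniform(-5, 5, size=200)
        t = np.arange(200.0)
        whole = relay_transitions(x, t, THR)
        relay = _Relay(THR)
        for k in range(0, 200, 37):
            relay.feed(x[k:k + 37], t[k:k + 37])
        assert relay.result().entries == whole.entries


class TestTransitionSequence:
    def test_rejects_non_alternating_states(self):
        with pytest.raises(ValueError, match="alternate"):
            TransitionSequence(entries=[(1.0, "A"), (2.0, "A")])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="increase"):
            TransitionSequence(entries=[(2.0, "A"), (2.0, "B")])


class TestResidenceDurations:
    def test_example(self):
        ts = TransitionSequence(entries=[(10.0, "A"), (25.0, "B"),
                                         (30.0, "A")], initial_state="B")
        durations = residence_durations(ts)
        assert durations == {"A": [15.0], "B": [5.0]}

    def test_single_transition_has_no_completed_stay(self):
        ts = TransitionSequence(entries=[(3.0, "A")], initial_state="B")
        assert residence_durations(ts) == {}

    def test_durations_tile_the_observed_span(self, rng):
        times = np.sort(rng.uniform(0, 100, size=21))
        entries = [(float(t), "AB"[i % 2]) for i, t in enumerate(times)]
        ts = TransitionSequence(entries=entries, initial_state="B")
        durations = residence_durations(ts)
        total = sum(sum(v) for v in durations.values())
        assert total == pytest.approx(times[-1] - times[0])


class TestLogBinnedDensity:
    def test_density_normalized(self, rng):
        d = rng.exponential(5.0, size=500) + 0.1
        edges, density = log_binned_density(d, 40)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0,
                                                                 abs=1e-12)
        assert len(edges) == 41

    def test_edges_span_data_geometrically(self, rng):
        d = rng.uniform(1.0, 100.0, size=200)
        edges, _ = log_binned_density(d, 10)
        assert edges[0] == d.min() and edges[-1] == d.max()
        ratios = edges[1:] / edges[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            log_binned_density([1.0, 1.0, 1.0], 10)
        with pytest.raises(ValueError):
            log_binned_density([2.0], 10)

    def test_two_state_histogram_shares_edges(self, rng):
        hist = residence_histogram(rng.exponential(5, 300) + 1,
                                   rng.exponential(9, 300) + 1, 50)
        hist.validate()
        widths = np.diff(hist.bin_edges)
        assert np.sum(hist.density_A * widths) == pytest.approx(1.0)
        assert np.sum(hist.density_B * widths) == pytest.approx(1.0)


class TestEscapeTime:
    def test_constructed_escape(self):
        # in the high-A state until t = 191, then crossing into B
        t = np.arange(0.0, 260.0, 1.0)
        x = np.where(t < 191, 5.0, -5.0)
        t_esc = escape_time(x, t, THR, start_state="A", low_state="B",
                            high_state="A")
        assert t_esc == 191.0

    def test_never_escaping_returns_none(self):
        t = np.arange(0.0, 50.0, 1.0)
        assert escape_time(np.full(50, 5.0), t, THR, start_state="A",
                           low_state="B", high_state="A") is None

    def test_agrees_with_first_foreign_relay_entry(self, rng):
        x = rng.uniform(-5, 5, size=300)
        t = np.arange(300.0)
        t_esc = escape_time(x, t, THR, start_state="A")
        ts = relay_transitions(x, t, THR, initial_state="A")
        foreign = [tt for tt, s in ts.entries if s != "A"]
        assert t_esc == (foreign[0] if foreign else None)


class TestCollectSwitchings:
    def test_chunked_projection_equals_single_run(self, trained_rc):
        r0 = trained_rc.end_state_A
        whole, final_w = closed_loop_projection(trained_rc, r0, 400)
        a, mid = closed_loop_projection(trained_rc, r0, 150)
        b, final_c = closed_loop_projection(trained_rc, mid, 250, t0=1.5)
        np.testing.assert_array_equal(final_w, final_c)
        np.testing.assert_array_equal(whole.points[150:], b.points)

    def test_multifunctional_rc_never_switches(self, trained_rc):
        ts, _ = collect_switchings(trained_rc, trained_rc.end_state_A,
                                   target_count=4, max_time=20.0,
                                   chunk_time=5.0)
        assert len(ts) == 0
        assert ts.complete is False

    def test_telegraph_signal_transition_count(self):
        # 10 completed swings fed through the incremental relay
        period = 20.0
        t = np.arange(0.0, 10 * period, 0.5)
        x = 5.0 * np.sign(np.sin(2 * np.pi * t / period) + 0.5)
        relay = _Relay(THR, low_state="B", high_state="A")
        relay.feed(x, t)
        ts = relay.result()
        swings = 0
        prev = np.sign(x[0])
        for v in np.sign(x[1:]):
            if v != prev:
                swings += 1
                prev = v
        assert len(ts) == swings


class TestEscapeTimeSweep:
    def test_stable_band_never_escapes_and_is_reproducible(
            self, realization, params, task8, scaled_train_config):
        grid = [0.45, 0.40]
        df1 = escape_time_sweep(realization, params, task8, grid,
                                scaled_train_config, max_time=50.0)
        df2 = escape_time_sweep(realization, params, task8, grid,
                                scaled_train_config, max_time=50.0)
        assert (~df1["escaped"]).all()
        assert df1.equals(df2)


class TestWindingCounts:
    def test_loop_tagging_on_constructed_signal(self):
        from rcswitching import TaskPair
        from rcswitching.dynamics import PlanarTrajectory
        task = TaskPair.seeing_double(6.5)
        t_loop = np.arange(0, 2 * np.pi, 0.01)
        seg_a = np.stack([6.5 + 5 * np.cos(t_loop), 5 * np.sin(t_loop)],
                         axis=1)
        seg_b = np.stack([-6.5 + 5 * np.cos(t_loop), 5 * np.sin(t_loop)],
                         axis=1)
        # A, B(1 loop), A(3 loops), B: the completed stays are the middle
        # B and A visits (the first A stay is open-ended and excluded); the
        # discontinuous splice costs up to half a turn, so tags are lower
        # bounds here
        pts = np.concatenate([seg_a, seg_b, seg_a, seg_a, seg_a, seg_b])
        times = 0.01 * np.arange(len(pts))
        traj = PlanarTrajectory(times=times, points=pts)
        ts = relay_transitions(traj.x, times, THR, low_state="B",
                               high_state="A")
        tagged = winding_counts(traj, ts, task)
        states = [s for s, _, _ in tagged]
        loops = [n for _, _, n in tagged]
        assert states == ["B", "A"]
        assert loops[0] >= 1 and loops[1] >= 2
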