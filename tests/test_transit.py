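import numpy as np
import pytest

from tunneltransit import (PositionState, TransitParams, assign_position,
                           assign_positions, count_utilization,
                           detect_transitions)

from conftest import make_series
from oracle_transit import brute_force_events, random_state_sequence

P = TransitParams()


class TestAssignPosition:
    @pytest.mark.parametrize("d,b,expected_kind", [
        (20.0, 3.0, "out_"),        # 20 > 14 + 2
        (11.9, 3.0, "in_"),         # 11.9 < 14 - 2
        (14.5, 3.0, "bt_"),         # in band, close to bottleneck
        (14.5, 6.0, "bt_unknown"),  # in band, too far across
        (16.0, 3.0, "bt_"),         # exact boundary stays in the band
        (12.0, 3.0, "bt_"),         # lower boundary likewise
    ])
    def test_single_tunnel(self, d, b, expected_kind):
        st = assign_position(d, {"p1": b}, {"p1": 14.0}, P)
        assert st.kind == expected_kind
        assert st.tunnel_id == "p1"

    def test_closest_tunnel_tie_breaks_canonically(self):
        st = assign_position(20.0, {"p1a": 4.0, "p1b": 4.0},
                             {"p1a": 14.0, "p1b": 14.0}, P,
                             tunnel_order=["p1a", "p1b"])
        assert st.tunnel_id == "p1a"

    def test_empty_tunnel_set_rejected(self):
        with pytest.raises(ValueError, match="empty tunnel"):
            assign_position(10.0, {}, {}, P)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        n = 200
        ds = make_series(rng.uniform(0, 30, n),
                         {"p1": rng.uniform(0, 12, n), "p2": rng.uniform(0, 12, n)},
                         L={"p1": 14.0, "p2": 11.0})
        vec = assign_positions(ds, P)
        for i in range(n):
            ref = assign_position(ds.d_cat[i],
                                  {t: ds.d_bt[t][i] for t in ds.tunnel_ids},
                                  {t: ds.L[t][i] for t in ds.tunnel_ids},
                                  P, frame=i, tunnel_order=list(ds.tunnel_ids))
            assert (vec[i].kind, vec[i].tunnel_id) == (ref.kind, ref.tunnel_id)


def states_of(kinds_tunnels):
    return [PositionState(kind=k, tunnel_id=t, frame=i)
            for i, (k, t) in enumerate(kinds_tunnels)]


def dummy_series(n, tunnels=("p1a", "p1b", "p2", "p3"), d_bt=None):
    d_bt = d_bt or {t: np.full(n, 5.0) for t in tunnels}
    return make_series(np.zeros(n), d_bt)


class TestDetectTransitions:
    def test_out_band_in_is_one_via_event(self):
        sts = states_of([("out_", "p2"), ("bt_", "p2"), ("in_", "p2")])
        ev = detect_transitions(sts, dummy_series(3), P)
        assert [(e.direction, e.mediation, e.category) for e in ev] == \
            [("out_in", "via_bottleneck", "p2")]

    def test_return_to_origin_discards_band_visit(self):
        sts = states_of([("out_", "p2"), ("bt_", "p2"), ("out_", "p2")])
        assert detect_transitions(sts, dummy_series(3), P) == []

    def test_last_band_frame_wins(self):
        sts = states_of([("in_", "p3"), ("bt_", "p3"), ("bt_", "p2"),
                         ("out_", "p2")])
        ev = detect_transitions(sts, dummy_series(4), P)
        assert [(e.direction, e.category) for e in ev] == [("in_out", "p2")]

    def test_unknown_band_frame_gives_unknown_category(self):
        sts = states_of([("out_", "p2"), ("bt_unknown", "p2"), ("in_", "p2")])
        ev = detect_transitions(sts, dummy_series(3), P)
        assert ev[0].category == "unknown"
        assert ev[0].mediation == "via_bottleneck"

    def test_direct_tolerance_swap_and_mixed(self):
        # out side closest to p1a, in side closest to p1b
        sts = states_of([("out_", "p1a"), ("in_", "p1b")])
        # in-side gap p1a - p1b = 0.4 <= 1.0: relabel, category p1a
        near = dummy_series(2, d_bt={
            "p1a": np.array([6.5, 4.4]), "p1b": np.array([7.5, 4.0])})
        ev = detect_transitions(sts, near, P)
        assert [(e.mediation, e.category) for e in ev] == [("direct", "p1a")]
        # gap 3.0 on both sides: mixed
        far = dummy_series(2, d_bt={
            "p1a": np.array([6.5, 7.0]), "p1b": np.array([9.5, 4.0])})
        ev = detect_transitions(sts, far, P)
        assert [(e.mediation, e.category) for e in ev] == [("direct", "mixed")]

    def test_direct_same_tunnel_both_sides(self):
        sts = states_of([("out_", "p2"), ("in_", "p2")])
        ev = detect_transitions(sts, dummy_series(2), P)
        assert [(e.direction, e.mediation, e.category) for e in ev] == \
            [("out_in", "direct", "p2")]

    def test_all_bulk_no_events(self):
        sts = states_of([("out_", "p2")] * 10)
        assert detect_transitions(sts, dummy_series(10), P) == []

    def test_empty_sequence_is_empty_list(self):
        assert detect_transitions([], dummy_series(0, d_bt={"p2": np.zeros(0)}), P) == []

    def test_leading_band_frames_produce_no_event(self):
        sts = states_of([("bt_", "p2"), ("bt_", "p3"), ("in_", "p2"),
                         ("bt_", "p2"), ("out_", "p2")])
        ev = detect_transitions(sts, dummy_series(5), P)
        assert [(e.direction, e.category) for e in ev] == [("in_out", "p2")]

    def test_events_time_ordered_and_non_overlapping(self):
        rng = np.random.default_rng(7)
        sts, d_bt = random_state_sequence(rng, ["p1a", "p2"], 300, PositionState)
        ds = make_series(np.zeros(300), d_bt)
        ev = detect_transitions(sts, ds, P)
        for a, b in zip(ev, ev[1:]):
            assert a.end_frame <= b.start_frame


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(42)
        tunnels = ["p1a", "p1b", "p2", "p3"]
        for _ in range(200):
            n = int(rng.integers(2, 60))
            sts, d_bt = random_state_sequence(rng, tunnels, n, PositionState)
            ds = make_series(np.zeros(n), d_bt)
            got = [(e.direction, e.mediation, e.category, e.start_frame,
                    e.end_frame) for e in detect_transitions(sts, ds, P)]
            assert got == brute_force_events(sts, ds.d_bt, P.dist_tolerance)


class TestStateMachineProperties:
    def test_frame_duplication_invariance(self):
        rng = np.random.default_rng(9)
        tunnels = ["p1a", "p2"]
        for _ in range(30):
            n = int(rng.integers(4, 30))
            sts, d_bt = random_state_sequence(rng, tunnels, n, PositionState)
            ds = make_series(np.zeros(n), d_bt)
            base = [(e.direction, e.mediation, e.category)
                    for e in detect_transitions(sts, ds, P)]
            # repeat a random frame 3x
            i = int(rng.integers(n))
            reps = np.concatenate([np.arange(i + 1), [i, i], np.arange(i + 1, n)])
            sts2 = [PositionState(sts[j].kind, sts[j].tunnel_id, k)
                    for k, j in enumerate(reps)]
            ds2 = make_series(np.zeros(len(reps)),
                              {t: d_bt[t][reps] for t in tunnels})
            dup = [(e.direction, e.mediation, e.category)
                   for e in detect_transitions(sts2, ds2, P)]
            assert dup == base

    def test_reversal_maps_directions(self):
        sts = states_of([("out_", "p2"), ("bt_", "p2"), ("in_", "p2"),
                         ("in_", "p2"), ("bt_", "p3"), ("out_", "p3")])
        ds = dummy_series(6)
        fwd = detect_transitions(sts, ds, P)
        rev_states = [PositionState(s.kind, s.tunnel_id, i)
                      for i, s in enumerate(reversed(sts))]
        rev = detect_transitions(rev_states, ds, P)
        flip = {"in_out": "out_in", "out_in": "in_out"}
        assert [(flip[e.direction], e.category) for e in reversed(rev)] == \
            [(e.direction, e.category) for e in fwd]


class TestUtilization:
    def make_events(self, spec):
        """spec: list of (scheme, replicate, trajectory, category)."""
        from tunneltransit import TransitionEvent
        return [TransitionEvent("out_in", "via_bottleneck" if c not in ("mixed",)
                                else "direct", c, 2 * i, 2 * i + 1,
                                metadata={"scheme": s, "replicate": r, "run_id": t})
                for i, (s, r, t, c) in enumerate(spec)]

    def test_replicate_mean_and_sample_std(self):
        spec = ([("bulk", "r1", "t1", "p2")] * 10
                + [("bulk", "r2", "t1", "p2")] * 20
                + [("bulk", "r3", "t1", "p2")] * 30)
        util = count_utilization(self.make_events(spec))
        row = util.per_scheme.loc["bulk"]
        assert row["p2_mean"] == pytest.approx(20.0)
        assert row["p2_std"] == pytest.approx(10.0)   # sample stdev of 10,20,30

    def test_fractions_normalise(self):
        spec = ([("b", "r1", "t1", "p2")] * 6 + [("b", "r1", "t1", "p1b")] * 3
                + [("b", "r1", "t1", "mixed")] * 1)
        util = count_utilization(self.make_events(spec))
        row = util.per_scheme.loc["b"]
        assert row["p2_frac"] == pytest.approx(0.6)
        assert row["p1b_frac"] == pytest.approx(0.3)
        assert row["mixed_frac"] == pytest.approx(0.1)

    def test_counts_sum_to_events(self):
        rng = np.random.default_rng(1)
        cats = ["p1a", "p2", "mixed", "unknown"]
        spec = [("b", f"r{rng.integers(1, 4)}", f"t{rng.integers(1, 6)}",
                 cats[rng.integers(len(cats))]) for _ in range(100)]
        events = self.make_events(spec)
        util = count_utilization(events)
        assert util.per_trajectory["total"].sum() == len(events)
        assert util.per_replicate["total"].sum() == len(events)

    def test_empty_input_gives_empty_tables(self):
        util = count_utilization([])
        assert len(util.per_trajectory) == 0
        assert len(util.per_scheme) == 0
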