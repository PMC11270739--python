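"""Brute-force reference for transition detection.

Independent of the production state machine: it simply lists all frames
with a general (in_/out_) state, pairs up consecutive frames whose sides
differ, and classifies each pair from the raw frames between them.
"""

from __future__ import annotations


def brute_force_events(states, d_bt, tol):
    """states: sequence of PositionState; d_bt: dict tunnel -> per-frame
    distances; returns [(direction, mediation, category, start, end)]."""
    general = [i for i, s in enumerate(states) if s.side is not None]
    events = []
    for a, b in zip(general, general[1:]):
        sa, sb = states[a], states[b]
        if sa.side == sb.side:
            continue
        band = [states[i] for i in range(a + 1, b) if states[i].is_band]
        if band:
            last = band[-1]
            category = last.tunnel_id if last.kind == "bt_" else "unknown"
            mediation = "via_bottleneck"
        else:
            mediation = "direct"
            ta, tb = sa.tunnel_id, sb.tunnel_id
            if ta == tb:
                category = ta
            elif d_bt[ta][b] - d_bt[tb][b] <= tol:
                category = ta
            elif d_bt[tb][a] - d_bt[ta][a] <= tol:
                category = tb
            else:
                category = "mixed"
        events.append((f"{sa.side}_{sb.side}", mediation, category, a, b))
    return events


def random_state_sequence(rng, tunnels, n, states_cls):
    """Random PositionState sequence plus consistent random d_bt arrays."""
    kinds = rng.choice(["in_", "out_", "bt_", "bt_unknown"], size=n,
                       p=[0.3, 0.3, 0.25, 0.15])
    tun = [tunnels[i] for i in rng.integers(0, len(tunnels), n)]
    states = [states_cls(kind=k, tunnel_id=t, frame=i)
              for i, (k, t) in enumerate(zip(kinds, tun))]
    d_bt = {t: rng.uniform(0.0, 10.0, n) for t in tunnels}
    return states, d_bt
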