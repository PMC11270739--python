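import numpy as np
import pytest

from tunneltransit import (DistanceSeries, PlannedTransit, PlantedEventPlan,
                           ToyNetworkSpec, TransitParams)


@pytest.fixture
def toy_spec():
    """Three-tunnel toy network with well-separated directions."""
    return ToyNetworkSpec(tunnels={
        "p1a": ((0.0, 0.0, 1.0), 14.0),
        "p1b": ((0.0, 1.0, 0.0), 16.0),
        "p2": ((1.0, 0.0, 0.0), 12.0),
    }, noise_sd=0.3)


@pytest.fixture
def params():
    return TransitParams()


def make_series(d_cat, d_bt, L=None, frame_interval=100.0, **meta):
    """Build a DistanceSeries from plain dict-of-list inputs."""
    d_cat = np.asarray(d_cat, dtype=float)
    d_bt = {t: np.asarray(v, dtype=float) for t, v in d_bt.items()}
    if L is None:
        L = {t: np.full_like(d_cat, 14.0) for t in d_bt}
    else:
        L = {t: (np.full_like(d_cat, v) if np.isscalar(v) else np.asarray(v, float))
             for t, v in L.items()}
    return DistanceSeries(d_cat, d_bt, L, frame_interval=frame_interval,
                          metadata=dict(meta))


def alternating_plan(tunnels, n_events, rng, first="out_in"):
    """A feasible plan of n alternating transits through random tunnels."""
    transits = []
    direction = first
    for _ in range(n_events):
        transits.append(PlannedTransit(
            tunnel_id=tunnels[rng.integers(len(tunnels))],
            direction=direction,
            dwell_frames=int(rng.integers(3, 7)),
            band_frames=int(rng.integers(1, 5))))
        direction = "in_out" if direction == "out_in" else "out_in"
    return PlantedEventPlan(transits)
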