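"""Tunnel-transit tracking: position assignment, transition detection,
and utilization counting.

The ligand's per-frame position relative to the tunnel network is reduced
to one of four states using the distance to the catalytic machinery
``d``, the instantaneous length ``L`` of the tunnel whose bottleneck is
closest to the ligand, and two cutoffs:

* ``out_``   — bulk: ``d > L + bt_cutoff_along``;
* ``in_``    — interior: ``d < L - bt_cutoff_along``;
* ``bt_``    — bottleneck band ``|d - L| <= bt_cutoff_along`` with the
  ligand within ``bt_cutoff_across`` of the bottleneck laterally;
* ``bt_unknown`` — in the band but far from every bottleneck.

A transition event is one completed crossing between bulk and interior,
either direct (consecutive ``in_``/``out_`` frames) or mediated by a visit
to the bottleneck band.  Direct crossings whose two endpoint frames
disagree about the closest tunnel are reconciled with a distance
tolerance; irreconcilable crossings are ``mixed``.  Band-mediated
crossings inherit the tunnel of the last band frame (``unknown`` if that
frame was ``bt_unknown``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import DistanceSeries

__all__ = [
    "TransitParams",
    "PositionState",
    "TransitionEvent",
    "UtilizationTable",
    "assign_position",
    "assign_positions",
    "detect_transitions",
    "track_transits",
    "count_utilization",
    "events_to_frame",
]

MIXED = "mixed"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class TransitParams:
    """Cutoffs of the transit tracker (Å)."""

    bt_cutoff_along: float = 2.0   # half-width of the bottleneck band along the tunnel axis
    bt_cutoff_across: float = 5.0  # max lateral distance from the bottleneck inside the band
    dist_tolerance: float = 1.0    # closest-tunnel swap tolerance for direct crossings

    def __post_init__(self) -> None:
        for name in ("bt_cutoff_along", "bt_cutoff_across", "dist_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PositionState:
    """Ligand position of one frame: kind plus the closest bottleneck."""

    kind: str        # "in_" | "out_" | "bt_" | "bt_unknown"
    tunnel_id: str   # closest bottleneck (defined for every kind)
    frame: int = 0

    @property
    def is_band(self) -> bool:
        return self.kind in ("bt_", "bt_unknown")

    @property
    def side(self) -> str | None:
        """'in'/'out' for general states, None inside the band."""
        return {"in_": "in", "out_": "out"}.get(self.kind)


@dataclass(frozen=True)
class TransitionEvent:
    direction: str                 # "in_out" | "out_in"
    mediation: str                 # "direct" | "via_bottleneck"
    category: str                  # tunnel id | "mixed" | "unknown"
    start_frame: int
    end_frame: int
    metadata: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise ValueError("event must span at least one frame pair")
        if self.mediation == "via_bottleneck" and self.category == MIXED:
            raise ValueError("band-mediated events are never mixed")
        if self.mediation == "direct" and self.category == UNKNOWN:
            raise ValueError("direct events are never unknown")


def assign_position(
    d_cat: float,
    d_bt: dict[str, float],
    L: dict[str, float],
    params: TransitParams = TransitParams(),
    frame: int = 0,
    tunnel_order: Sequence[str] | None = None,
) -> PositionState:
    """Classify a single frame.  Ties on the closest bottleneck break by
    canonical tunnel order."""
    order = list(tunnel_order) if tunnel_order is not None else list(d_bt)
    if not order:
        raise ValueError("empty tunnel set")
    closest = min(order, key=lambda t: (d_bt[t], order.index(t)))
    length = L[closest]
    along = params.bt_cutoff_along
    if d_cat > length + along:
        kind = "out_"
    elif d_cat < length - along:
        kind = "in_"
    elif d_bt[closest] <= params.bt_cutoff_across:
        kind = "bt_"
    else:
        kind = "bt_unknown"
    return PositionState(kind, closest, frame)


def assign_positions(
    ds: DistanceSeries,
    params: TransitParams = TransitParams(),
) -> list[PositionState]:
    """Vectorised per-frame position assignment for a whole trajectory."""
    tunnels = list(ds.tunnel_ids)
    if not tunnels:
        raise ValueError("empty tunnel set")
    D = np.column_stack([ds.d_bt[t] for t in tunnels])    # (n, T)
    Lm = np.column_stack([ds.L[t] for t in tunnels])
    closest = np.argmin(D, axis=1)                        # first minimum wins: canonical order
    n = ds.n_frames
    rows = np.arange(n)
    length = Lm[rows, closest]
    b = D[rows, closest]
    d = ds.d_cat
    along = params.bt_cutoff_along
    kinds = np.where(
        d > length + along, "out_",
        np.where(d < length - along, "in_",
                 np.where(b <= params.bt_cutoff_across, "bt_", "bt_unknown")))
    return [PositionState(str(kinds[i]), tunnels[closest[i]], i) for i in range(n)]


def _direct_category(
    d_bt_start: dict[str, float],
    d_bt_end: dict[str, float],
    t_start: str,
    t_end: str,
    tol: float,
) -> str:
    """Category of a direct crossing whose endpoints name tunnels
    ``t_start`` and ``t_end``.

    If they agree, that tunnel.  Otherwise a side may be relabelled to the
    other side's tunnel when that tunnel is within ``tol`` of the side's
    own closest distance; the end side is tried first, then the start
    side; failing both the crossing is mixed.
    """
    if t_start == t_end:
        return t_start
    if d_bt_end[t_start] - d_bt_end[t_end] <= tol:
        return t_start
    if d_bt_start[t_end] - d_bt_start[t_start] <= tol:
        return t_end
    return MIXED


def detect_transitions(
    states: Sequence[PositionState],
    ds: DistanceSeries,
    params: TransitParams = TransitParams(),
    metadata: dict | None = None,
) -> list[TransitionEvent]:
    """Run the transit state machine over one trajectory.

    The machine tracks the last general side (``in``/``out``) and, while
    the ligand sits in the bottleneck band, a temporary bottleneck label
    updated on every band frame (last write wins).  Crossings complete
    when the ligand reaches the side opposite its origin; returning to the
    origin side discards the band visit.  Leading band frames before any
    general-side frame produce no event.
    """
    meta = dict(metadata or {})
    events: list[TransitionEvent] = []
    general: str | None = None      # side of the last in_/out_ frame
    general_frame = -1
    general_tunnel = ""             # closest tunnel at that frame
    temp_bt: str | None = None      # tunnel id | UNKNOWN while banded

    def d_bt_at(i: int) -> dict[str, float]:
        return {t: float(ds.d_bt[t][i]) for t in ds.tunnel_ids}

    for st in states:
        if st.is_band:
            if general is not None:
                temp_bt = st.tunnel_id if st.kind == "bt_" else UNKNOWN
            continue
        side = st.side
        if general is None:
            general, general_frame, general_tunnel = side, st.frame, st.tunnel_id
            continue
        if side == general:
            # return to origin (or plain dwell): band visit discarded
            temp_bt = None
            general_frame, general_tunnel = st.frame, st.tunnel_id
            continue
        if temp_bt is not None:
            category = temp_bt
            mediation = "via_bottleneck"
        else:
            category = _direct_category(
                d_bt_at(general_frame), d_bt_at(st.frame),
                general_tunnel, st.tunnel_id, params.dist_tolerance)
            mediation = "direct"
        events.append(TransitionEvent(
            direction=f"{general}_{side}",
            mediation=mediation,
            category=category,
            start_frame=general_frame,
            end_frame=st.frame,
            metadata=meta,
        ))
        general, general_frame, general_tunnel = side, st.frame, st.tunnel_id
        temp_bt = None
    return events


def track_transits(
    ds: DistanceSeries,
    params: TransitParams = TransitParams(),
) -> list[TransitionEvent]:
    """Convenience: assign positions then detect transitions for one series."""
    states = assign_positions(ds, params)
    return detect_transitions(states, ds, params, metadata=dict(ds.metadata))


def events_to_frame(events: Iterable[TransitionEvent]) -> pd.DataFrame:
    """Flatten events (plus their trajectory metadata) into a table."""
    rows = []
    for ev in events:
        rec = {
            "trajectory": ev.metadata.get("run_id", ""),
            "scheme": ev.metadata.get("scheme", ""),
            "replicate": ev.metadata.get("replicate", ""),
            "start_frame": ev.start_frame,
            "end_frame": ev.end_frame,
            "direction": ev.direction,
            "mediation": ev.mediation,
            "category": ev.category,
        }
        rows.append(rec)
    cols = ["trajectory", "scheme", "replicate", "start_frame", "end_frame",
            "direction", "mediation", "category"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class UtilizationTable:
    """Tunnel-utilization summary at three levels of aggregation.

    ``per_trajectory`` — event counts per trajectory × category;
    ``per_replicate`` — counts summed over each replicate's trajectories;
    ``per_scheme`` — mean ± sample standard deviation (ddof=1) of the
    replicate totals within each scheme, plus relative fractions.
    """

    per_trajectory: pd.DataFrame
    per_replicate: pd.DataFrame
    per_scheme: pd.DataFrame
    categories: tuple[str, ...]


def count_utilization(
    events: Iterable[TransitionEvent],
    categories: Sequence[str] | None = None,
) -> UtilizationTable:
    """Count unique transitions per category and aggregate across
    trajectories, replicates and schemes.

    Each completed crossing counts once; repeated crossings are separate
    events.  ``categories`` fixes the column order (tunnel ids in
    canonical order, then mixed/unknown); by default it is inferred from
    the events.
    """
    df = events_to_frame(events)
    if categories is None:
        seen = [c for c in df["category"].unique()] if len(df) else []
        tunnels = sorted(c for c in seen if c not in (MIXED, UNKNOWN))
        categories = tuple(tunnels) + (MIXED, UNKNOWN)
    categories = tuple(categories)

    def pivot(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        if len(frame) == 0:
            return pd.DataFrame(columns=list(categories) + ["total"])
        counts = (frame.groupby(keys + ["category"]).size().unstack(fill_value=0)
                  .reindex(columns=categories, fill_value=0))
        counts["total"] = counts.sum(axis=1)
        return counts

    per_traj = pivot(df, ["scheme", "replicate", "trajectory"])
    per_rep = pivot(df, ["scheme", "replicate"])

    scheme_rows = []
    if len(per_rep):
        for scheme, block in per_rep.groupby(level="scheme"):
            rec: dict[str, object] = {"scheme": scheme, "n_replicates": len(block)}
            total_mean = float(block["total"].mean())
            for cat in categories:
                vals = block[cat].to_numpy(dtype=float)
                rec[f"{cat}_mean"] = float(vals.mean())
                rec[f"{cat}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                rec[f"{cat}_frac"] = (float(vals.mean()) / total_mean) if total_mean else 0.0
            rec["total_mean"] = total_mean
            scheme_rows.append(rec)
    per_scheme = pd.DataFrame(scheme_rows)
    if len(per_scheme):
        per_scheme = per_scheme.set_index("scheme")
    return UtilizationTable(per_traj, per_rep, per_scheme, categories)
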