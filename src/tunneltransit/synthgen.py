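"""Synthetic inputs with planted ground truth.

Every analysis stage in this package is validated against data whose
answer is known by construction: toy tunnel networks with closed-form
landmark geometry, ligand walks that execute a scripted list of
bulk↔interior transits through chosen bottlenecks, Markov-chain
trajectories sampled from a known transition matrix (with analytic
MFPTs), and metastable-state ensembles drawn from separated distance
profiles.  Generators are bit-reproducible given a seed.

The walks emulate only the statistical structure the analysis assumes —
metastable dwells, band crossings near a bottleneck, Gaussian positional
jitter — not the physics of any particular protein.  In the default
"clean" mode a margin of 2·noise_sd (at least 0.5 Å) is kept around every
decision boundary so planted events are recovered exactly; hard mode
removes the margin to exercise the tolerance rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CoordinateTrajectory, TunnelNetwork
from .transit import TransitParams

__all__ = [
    "ToyNetworkSpec",
    "PlannedTransit",
    "PlantedEventPlan",
    "MarkovChainSample",
    "make_toy_network",
    "simulate_ligand_walk",
    "simulate_markov_chain",
    "simulate_region_occupancy",
    "generate_metastable_ensembles",
]


@dataclass
class ToyNetworkSpec:
    """Geometry of a toy tunnel network.

    The catalytic machinery sits at the origin; each tunnel's bottleneck
    COM lies at ``length * direction``.  Lengths are in Å and must exceed
    the bottleneck band half-width so all four position states exist.
    """

    tunnels: dict[str, tuple[Sequence[float], float]]   # id -> (direction, length)
    noise_sd: float = 0.3
    params: TransitParams = field(default_factory=TransitParams)

    def __post_init__(self) -> None:
        if not self.tunnels:
            raise ValueError("need at least one tunnel")
        dirs = {}
        for tid, (u, length) in self.tunnels.items():
            u = np.asarray(u, dtype=float)
            u = u / np.linalg.norm(u)
            if length <= self.params.bt_cutoff_along:
                raise ValueError(f"tunnel {tid}: length must exceed bt_cutoff_along")
            for other, v in dirs.items():
                if abs(float(u @ v)) > 0.999:
                    raise ValueError(f"tunnels {tid} and {other} have duplicate directions")
            dirs[tid] = u
        self._dirs = dirs

    def direction(self, tid: str) -> np.ndarray:
        return self._dirs[tid]

    def length(self, tid: str) -> float:
        return float(self.tunnels[tid][1])

    @property
    def tunnel_ids(self) -> tuple[str, ...]:
        return tuple(self.tunnels)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


def make_toy_network(spec: ToyNetworkSpec) -> tuple[TunnelNetwork, dict[str, np.ndarray]]:
    """Landmark definition plus static landmark atom coordinates.

    Each group's member atoms are placed with offsets that sum to zero,
    so the geometric COM equals the intended landmark point exactly and
    the closed-form tunnel lengths are reproduced by the geometry stage.
    """
    coords: dict[str, np.ndarray] = {}
    # catalytic machinery: equilateral-ish triad around the origin
    cat_members = ("CAT1", "CAT2", "CAT3")
    offsets = np.array([[0.8, 0.0, 0.0], [-0.4, 0.7, 0.0], [-0.4, -0.7, 0.0]])
    for m, off in zip(cat_members, offsets):
        coords[f"{m}/P"] = off.copy()
    tunnels: dict[str, tuple[str, ...]] = {}
    for i, tid in enumerate(spec.tunnel_ids, start=1):
        u = spec.direction(tid)
        com = spec.length(tid) * u
        v, _ = _perp_basis(u)
        # "BT" residue family, ids <i>1 / <i>2: PDB-safe (<=3 char res names)
        members = (f"BT{i}1", f"BT{i}2")
        coords[f"{members[0]}/P"] = com + 0.9 * v
        coords[f"{members[1]}/P"] = com - 0.9 * v
        tunnels[tid] = members
    net = TunnelNetwork(catalytic=cat_members, tunnels=tunnels)
    return net, coords


@dataclass
class PlannedTransit:
    tunnel_id: str
    direction: str          # "out_in" | "in_out"
    dwell_frames: int = 5   # frames to dwell at the destination
    band_frames: int = 3    # frames spent inside the bottleneck band

    def __post_init__(self) -> None:
        if self.direction not in ("out_in", "in_out"):
            raise ValueError("direction must be out_in or in_out")
        if self.dwell_frames < 1 or self.band_frames < 1:
            raise ValueError("dwell and band frames must be >= 1")


@dataclass
class PlantedEventPlan:
    transits: list[PlannedTransit]
    lead_frames: int = 5

    def __post_init__(self) -> None:
        if self.lead_frames < 1:
            raise ValueError("lead_frames must be >= 1")


def simulate_ligand_walk(
    spec: ToyNetworkSpec,
    plan: PlantedEventPlan,
    seed: int = 0,
    frame_interval: float = 100.0,
    hard: bool = False,
    metadata: dict | None = None,
) -> tuple[CoordinateTrajectory, list[dict]]:
    """Scripted ligand walk executing the plan's bulk↔interior transits.

    The ligand COM moves radially along a tunnel's axis through the
    bottleneck band (passing within ``bt_cutoff_across`` of the
    bottleneck), dwells at safe radii on each side, and travels between
    tunnel axes on spherical arcs that stay clear of every band.
    Gaussian jitter of sd ``spec.noise_sd`` is added to every ligand
    position.  Returns the coordinate trajectory (ligand + landmarks)
    and the exact expected transition-event list.
    """
    p = spec.params
    along = p.bt_cutoff_along
    noise = spec.noise_sd
    margin = 0.0 if hard else max(2.0 * noise, 0.5)
    lengths = {t: spec.length(t) for t in spec.tunnel_ids}
    r_travel_out = max(lengths.values()) + along + margin + 2.0
    r_in = min(lengths.values()) - along - margin - 1.0
    if r_in <= 0.5:
        raise ValueError("infeasible plan: shortest tunnel leaves no interior dwell radius")

    def r_stage_out(tid: str) -> float:
        return lengths[tid] + along + margin + 1.0

    path: list[np.ndarray] = []
    truth: list[dict] = []

    def radial(u: np.ndarray, r0: float, r1: float) -> None:
        n = max(1, int(math.ceil(abs(r1 - r0) / 1.0)))
        for r in np.linspace(r0, r1, n + 1)[1:]:
            path.append(r * u)

    def arc(u0: np.ndarray, u1: np.ndarray, r: float) -> None:
        dot = float(np.clip(u0 @ u1, -1.0, 1.0))
        ang = math.acos(dot)
        if ang < 1e-9:
            return
        n = max(1, int(math.ceil(ang / 0.15)))
        axis_perp = u1 - dot * u0
        axis_perp /= np.linalg.norm(axis_perp)
        for t in np.linspace(0.0, ang, n + 1)[1:]:
            path.append(r * (math.cos(t) * u0 + math.sin(t) * axis_perp))

    side: str | None = None
    cur_dir = np.zeros(3)
    for step, tr in enumerate(plan.transits):
        if tr.tunnel_id not in lengths:
            raise ValueError(f"infeasible plan at step {step}: unknown tunnel {tr.tunnel_id!r}")
        origin = "out" if tr.direction == "out_in" else "in"
        dest = "in" if origin == "out" else "out"
        u = spec.direction(tr.tunnel_id)
        L = lengths[tr.tunnel_id]
        if side is None:
            side = origin
            cur_dir = u
            r0 = r_stage_out(tr.tunnel_id) if origin == "out" else r_in
            for _ in range(plan.lead_frames):
                path.append(r0 * cur_dir)
        elif side != origin:
            raise ValueError(
                f"infeasible plan at step {step}: {tr.direction} transit "
                f"requested while the ligand is {side}side")
        else:
            # same-side travel to this tunnel's axis
            if origin == "out":
                radial(cur_dir, np.linalg.norm(path[-1]), r_travel_out)
                arc(cur_dir, u, r_travel_out)
                radial(u, r_travel_out, r_stage_out(tr.tunnel_id))
            else:
                arc(cur_dir, u, r_in)
            cur_dir = u
        # cross the band along the axis
        delta = min(0.4 * along, max(0.25, 0.5 * along - margin / 2))
        start_frame = len(path) - 1
        if origin == "out":
            band_r = np.linspace(L + along - delta, L - along + delta, tr.band_frames + 2)[1:-1]
            dest_r = r_in
        else:
            band_r = np.linspace(L - along + delta, L + along - delta, tr.band_frames + 2)[1:-1]
            dest_r = r_stage_out(tr.tunnel_id)
        for r in band_r:
            path.append(r * u)
        radial(u, band_r[-1], dest_r)
        end_frame = len(path) - 1
        for _ in range(tr.dwell_frames):
            path.append(dest_r * u)
        truth.append({
            "direction": tr.direction,
            "mediation": "via_bottleneck",
            "category": tr.tunnel_id,
            "start_frame": start_frame,
            "end_frame": end_frame,
        })
        side = dest
        cur_dir = u

    if side is None:   # no transits: hover in bulk along the first tunnel axis
        u = spec.direction(spec.tunnel_ids[0])
        for _ in range(plan.lead_frames):
            path.append(r_travel_out * u)

    lig = np.asarray(path)
    rng = np.random.default_rng(seed)
    lig = lig + rng.normal(0.0, noise, lig.shape)

    net, lm_coords = make_toy_network(spec)
    atom_ids = ["LIG/C1"] + list(lm_coords)
    n = lig.shape[0]
    coords = np.empty((n, len(atom_ids), 3))
    coords[:, 0, :] = lig
    for j, aid in enumerate(lm_coords, start=1):
        coords[:, j, :] = lm_coords[aid]
    traj = CoordinateTrajectory(coords, atom_ids, frame_interval=frame_interval,
                                metadata=dict(metadata or {}))
    return traj, truth


@dataclass
class MarkovChainSample:
    """Discrete chain sampled from a known transition matrix, mapped to
    feature space with Gaussian jitter."""

    states: np.ndarray          # (n_steps,) int
    features: np.ndarray        # (n_steps, d)
    P_true: np.ndarray
    centers: np.ndarray
    frame_interval: float

    def analytic_mfpt(self, source: Sequence[int], sink: Sequence[int],
                      lag_time: float = 1.0) -> float:
        """Exact MFPT of the generating chain (linear-system solution)."""
        from .msm import mfpt, stationary_distribution
        pi = stationary_distribution(self.P_true)
        return mfpt(self.P_true, source, sink, lag_time=lag_time, pi=pi)


def simulate_markov_chain(
    P_true: np.ndarray,
    centers: np.ndarray,
    n_steps: int,
    frame_interval: float = 100.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    start: int | None = None,
) -> MarkovChainSample:
    """Sample a trajectory from a known row-stochastic, irreducible chain."""
    P = np.asarray(P_true, dtype=float)
    k = P.shape[0]
    if P.shape != (k, k) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("P_true must be square and row-stochastic")
    from scipy.sparse.csgraph import connected_components
    n_comp, _ = connected_components(P > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("P_true must be irreducible")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] != k:
        raise ValueError("need one center per state")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_steps, dtype=int)
    s = int(start) if start is not None else int(rng.integers(k))
    u = rng.random(n_steps)
    for t in range(n_steps):
        states[t] = s
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        s = min(s, k - 1)
    X = centers[states] + rng.normal(0.0, noise_sd, (n_steps, centers.shape[1]))
    return MarkovChainSample(states, X, P, centers, frame_interval)


def simulate_region_occupancy(
    fractions: Sequence[float],
    n_frames: int,
    r_cavity: float = 5.0,
    r_bulk: float = 19.0,
    bulk_max: float = 40.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """d_cat series with planted (cavity, tunnel, bulk) occupancy.

    Each frame's region is drawn from the planted fractions and its
    distance uniformly within the region.  Returns ``(d_cat, region)``
    where region is 0/1/2 for cavity/tunnel/bulk.
    """
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (3,) or not np.isclose(frac.sum(), 1.0):
        raise ValueError("fractions must be 3 values summing to 1")
    rng = np.random.default_rng(seed)
    region = rng.choice(3, size=n_frames, p=frac)
    lo = np.array([0.0, r_cavity + 1e-9, r_bulk + 1e-9])
    hi = np.array([r_cavity, r_bulk, bulk_max])
    d = rng.uniform(lo[region], hi[region])
    return d, region


def generate_metastable_ensembles(
    profiles: np.ndarray,
    noise_sd: float,
    n_reps: int = 3,
    n_frames: int = 1000,
    seed: int = 0,
    presence: np.ndarray | None = None,
    probabilities: Sequence[float] | None = None,
    scheme: str = "synth",
):
    """Metastable-state ensembles drawn around planted distance profiles.

    ``profiles`` is (k, n_distances); each replicate gets one ensemble per
    profile present in it (``presence`` is an optional k × n_reps boolean
    mask).  Returns ``(ensembles, planted)`` where ``planted`` maps state
    id -> planted profile index.
    """
    from .uls import StateEnsemble

    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    k = profiles.shape[0]
    if presence is None:
        presence = np.ones((k, n_reps), dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != (k, n_reps):
        raise ValueError("presence mask must be (n_profiles, n_reps)")
    rng = np.random.default_rng(seed)
    ensembles: list = []
    planted: dict[str, int] = {}
    for rep in range(n_reps):
        for prof in range(k):
            if not presence[prof, rep]:
                continue
            X = profiles[prof] + rng.normal(0.0, noise_sd, (n_frames, profiles.shape[1]))
            X = np.clip(X, 0.0, None)
            sid = f"{scheme}-r{rep + 1}-s{prof}"
            prob = float(probabilities[prof]) if probabilities is not None else None
            ensembles.append(StateEnsemble(
                state_id=sid, scheme=scheme, replicate=f"r{rep + 1}",
                distances=X, probability=prob))
            planted[sid] = prof
    return ensembles, planted
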