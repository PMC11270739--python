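"""Landmark geometry: distance series and region classification.

A ligand's position relative to an enzyme tunnel network is summarised by
three families of centre-of-mass (COM) distances measured per frame:

* ``d_cat`` — ligand COM to the COM of the catalytic-machinery residues,
* ``d_bt[T]`` — ligand COM to the COM of the bottleneck residues of tunnel T,
* ``L[T]`` — catalytic COM to bottleneck COM of tunnel T (the instantaneous
  tunnel length).

Frames are classified into three regions by ``d_cat``: the active-site
cavity (0–5 Å by default), the tunnel region (5–19 Å) and bulk solvent
(> 19 Å).  The upper cutoff corresponds to the average length of the
transport tunnels of the system under study and is a plain configuration
value here.  Boundaries use a half-open-above convention: a frame exactly
at a cutoff belongs to the inner region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TunnelNetwork",
    "CoordinateTrajectory",
    "DistanceSeries",
    "REGIONS",
    "group_com",
    "build_distance_series",
    "classify_region",
    "region_fractions",
    "epoch_region_fractions",
]

REGIONS = ("cavity", "tunnel", "bulk")

#: Monoisotopic-ish average masses for the elements that occur in the
#: structures we read; COM falls back to geometric weighting when an
#: element is unknown.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}


@dataclass(frozen=True)
class TunnelNetwork:
    """Landmark definition: one catalytic residue group plus one bottleneck
    residue group per tunnel.

    Parameters
    ----------
    catalytic : sequence of str
        Residue (or atom) identifiers of the catalytic machinery, e.g.
        ``["N38", "D108", "W109"]``.
    tunnels : mapping of str -> sequence of str
        Ordered map tunnel id -> bottleneck residue group.  Declaration
        order is the canonical tunnel order used for tie-breaking.
    """

    catalytic: tuple[str, ...]
    tunnels: Mapping[str, tuple[str, ...]]

    def __init__(self, catalytic: Sequence[str], tunnels: Mapping[str, Sequence[str]]):
        if not catalytic:
            raise ValueError("empty landmark group: catalytic")
        if not tunnels:
            raise ValueError("a tunnel network needs at least one tunnel")
        tun = {}
        for tid, group in tunnels.items():
            if not group:
                raise ValueError(f"empty landmark group: tunnel {tid!r}")
            tun[str(tid)] = tuple(group)
        object.__setattr__(self, "catalytic", tuple(catalytic))
        object.__setattr__(self, "tunnels", tun)

    @property
    def tunnel_ids(self) -> tuple[str, ...]:
        """Tunnel ids in canonical (declaration) order."""
        return tuple(self.tunnels)


@dataclass
class CoordinateTrajectory:
    """Per-frame 3D positions (Å) for a fixed atom set.

    ``atom_ids`` are strings of the form ``"RES/NAME"`` (e.g. ``"N38/CA"``,
    ``"LIG/C1"``); the part before the slash is the residue tag that
    landmark groups select on.  A bare tag (no slash) is also accepted.
    """

    coords: np.ndarray                 # (n_frames, n_atoms, 3)
    atom_ids: list[str]
    masses: np.ndarray | None = None   # (n_atoms,) amu, optional
    frame_interval: float = 100.0      # ps per saved frame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_ids):
            raise ValueError("coords second axis must match atom_ids")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom_ids must be unique")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.atom_ids),):
                raise ValueError("masses must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def residue_tags(self) -> list[str]:
        return [a.split("/", 1)[0] for a in self.atom_ids]

    def select(self, group: Sequence[str]) -> np.ndarray:
        """Indices of atoms whose id or residue tag matches a group member."""
        if not group:
            raise ValueError("empty landmark group")
        tags = self.residue_tags()
        idx: list[int] = []
        for member in group:
            hits = [i for i, (aid, tag) in enumerate(zip(self.atom_ids, tags))
                    if aid == member or tag == member]
            if not hits:
                raise KeyError(f"landmark member {member!r} not found in trajectory")
            idx.extend(h for h in hits if h not in idx)
        return np.asarray(idx, dtype=int)


def group_com(
    frame: np.ndarray,
    indices: np.ndarray | Sequence[int],
    masses: np.ndarray | None = None,
    weights: str = "geometric",
) -> np.ndarray:
    """Centre of mass of a group of atoms in one frame (or a stack of frames).

    Parameters
    ----------
    frame : array, (..., n_atoms, 3)
    indices : atom indices of the group
    masses : per-atom masses for the whole frame; required for
        ``weights="mass"``
    weights : ``"geometric"`` (plain mean) or ``"mass"`` (mass-weighted)
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty landmark group")
    pts = np.asarray(frame, dtype=float)[..., indices, :]
    if weights == "geometric":
        return pts.mean(axis=-2)
    if weights == "mass":
        if masses is None:
            raise ValueError("mass weighting requested but no masses given")
        w = np.asarray(masses, dtype=float)[indices]
        return (pts * w[..., :, None]).sum(axis=-2) / w.sum()
    raise ValueError(f"unknown weighting {weights!r}")


@dataclass
class DistanceSeries:
    """Per-frame landmark distances for one trajectory.

    The substrate of every downstream stage: region classification,
    transit tracking, MSM featurisation and fingerprints all read from
    this container.
    """

    d_cat: np.ndarray                      # (n_frames,)
    d_bt: dict[str, np.ndarray]            # tunnel id -> (n_frames,)
    L: dict[str, np.ndarray]               # tunnel id -> (n_frames,)
    frame_interval: float = 100.0          # ps
    metadata: dict = field(default_factory=dict)  # scheme/replicate/epoch/run

    def __post_init__(self) -> None:
        self.d_cat = np.asarray(self.d_cat, dtype=float)
        self.d_bt = {t: np.asarray(v, dtype=float) for t, v in self.d_bt.items()}
        self.L = {t: np.asarray(v, dtype=float) for t, v in self.L.items()}
        n = self.d_cat.shape[0]
        if set(self.d_bt) != set(self.L):
            raise ValueError("d_bt and L must cover the same tunnels")
        for t in self.d_bt:
            if self.d_bt[t].shape != (n,) or self.L[t].shape != (n,):
                raise ValueError(f"distance arrays for tunnel {t!r} have wrong length")
        all_vals = np.concatenate([self.d_cat] + [self.d_bt[t] for t in self.d_bt]
                                  + [self.L[t] for t in self.L]) if n else self.d_cat
        if n and (all_vals < 0).any():
            raise ValueError("distances must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.d_cat.shape[0]

    @property
    def tunnel_ids(self) -> tuple[str, ...]:
        return tuple(self.d_bt)

    def features(self) -> np.ndarray:
        """(n_frames, 1 + n_tunnels) matrix [d_cat, d_bt_T...] in canonical order."""
        cols = [self.d_cat] + [self.d_bt[t] for t in self.d_bt]
        return np.column_stack(cols)


def build_distance_series(
    traj: CoordinateTrajectory,
    net: TunnelNetwork,
    ligand: Sequence[str] = ("LIG",),
    weights: str | None = None,
) -> DistanceSeries:
    """Compute the per-frame COM distance series for one trajectory.

    ``L[T]`` is recomputed every frame from the same coordinates (landmark
    stability is a property of the input, not an assumption of this code).
    ``weights=None`` selects mass weighting when masses are available and
    geometric weighting otherwise.
    """
    if weights is None:
        weights = "mass" if traj.masses is not None else "geometric"
    bad = np.argwhere(~np.isfinite(traj.coords))
    if bad.size:
        raise ValueError(f"non-finite coordinate in frame {int(bad[0][0])}")

    lig_idx = traj.select(ligand)
    cat_idx = traj.select(net.catalytic)
    lig = group_com(traj.coords, lig_idx, traj.masses, weights)
    cat = group_com(traj.coords, cat_idx, traj.masses, weights)
    d_cat = np.linalg.norm(lig - cat, axis=-1)
    d_bt: dict[str, np.ndarray] = {}
    length: dict[str, np.ndarray] = {}
    for tid in net.tunnel_ids:
        bt = group_com(traj.coords, traj.select(net.tunnels[tid]), traj.masses, weights)
        d_bt[tid] = np.linalg.norm(lig - bt, axis=-1)
        length[tid] = np.linalg.norm(cat - bt, axis=-1)
    return DistanceSeries(d_cat, d_bt, length,
                          frame_interval=traj.frame_interval,
                          metadata=dict(traj.metadata))


def classify_region(
    ds: DistanceSeries | np.ndarray,
    r_cavity: float = 5.0,
    r_bulk: float = 19.0,
) -> np.ndarray:
    """Label every frame cavity / tunnel / bulk from ``d_cat``.

    Cavity is ``d_cat <= r_cavity``, tunnel is ``r_cavity < d_cat <= r_bulk``,
    bulk is ``d_cat > r_bulk`` — a total partition, monotone in ``d_cat``.
    """
    if not 0 < r_cavity < r_bulk:
        raise ValueError(f"need 0 < r_cavity < r_bulk, got {r_cavity}, {r_bulk}")
    d = ds.d_cat if isinstance(ds, DistanceSeries) else np.asarray(ds, dtype=float)
    labels = np.where(d <= r_cavity, "cavity", np.where(d <= r_bulk, "tunnel", "bulk"))
    return labels.astype(object)


def region_fractions(labels: np.ndarray) -> dict[str, float]:
    """Fraction of frames in each region; keys always all three regions."""
    labels = np.asarray(labels)
    n = max(labels.size, 1)
    return {r: float((labels == r).sum()) / n for r in REGIONS}


def epoch_region_fractions(
    series: Sequence[DistanceSeries],
    r_cavity: float = 5.0,
    r_bulk: float = 19.0,
) -> pd.DataFrame:
    """Per-epoch region counts and fractions across a set of trajectories.

    Every series must carry ``epoch`` metadata.  Rows are indexed by epoch;
    count columns sum to the epoch's total frames and fraction columns sum
    to 1.
    """
    counts: dict[object, np.ndarray] = {}
    for ds in series:
        if "epoch" not in ds.metadata:
            raise ValueError("distance series without epoch metadata")
        epoch = ds.metadata["epoch"]
        labels = classify_region(ds, r_cavity, r_bulk)
        row = counts.setdefault(epoch, np.zeros(3, dtype=int))
        for k, r in enumerate(REGIONS):
            row[k] += int((labels == r).sum())
    if not counts:
        raise ValueError("no distance series given")
    rows = []
    for epoch in sorted(counts):
        c = counts[epoch]
        total = int(c.sum())
        rec: dict[str, object] = {"epoch": epoch, "n_frames": total}
        for k, r in enumerate(REGIONS):
            rec[f"n_{r}"] = int(c[k])
        for k, r in enumerate(REGIONS):
            rec[f"frac_{r}"] = c[k] / total if total else 0.0
        rows.append(rec)
    return pd.DataFrame(rows).set_index("epoch")
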