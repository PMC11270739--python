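"""Bulk-scheme seed placement: an equally spaced grid of candidate ligand
positions around the protein, clash-filtered and deterministically
subselected.

The grid spans the protein's axis-aligned bounding box expanded by a
padding on every side, with nx × ny × nz points at cell centres (a
corner-lattice registration is available by flag).  Candidates closer
than a clash cutoff to any protein atom are dropped; survivors are ranked
by their distance to the protein surface (most solvent-exposed first)
with a seeded shuffle breaking ties, and the top n are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SeedSet", "grid_seeds", "select_seeds"]


@dataclass
class SeedSet:
    points: np.ndarray          # (n, 3) Å
    grid_index: np.ndarray      # index of each point in the candidate grid
    min_protein_dist: np.ndarray
    scheme: str = "bulk"

    def __post_init__(self) -> None:
        if len({tuple(p) for p in np.round(self.points, 9)}) != len(self.points):
            raise ValueError("seed points must be unique")


def grid_seeds(
    protein_coords: np.ndarray,
    nx: int = 5,
    ny: int = 5,
    nz: int = 5,
    padding: float = 5.0,
    mode: str = "centers",
) -> np.ndarray:
    """Candidate grid over the padded bounding box of the protein.

    ``mode="centers"`` places points at cell centres of the padded box;
    ``mode="corners"`` places an inclusive corner lattice.
    """
    P = np.atleast_2d(np.asarray(protein_coords, dtype=float))
    if P.size == 0:
        raise ValueError("empty protein coordinates")
    if min(nx, ny, nz) < 1:
        raise ValueError("grid dimensions must be >= 1")
    lo = P.min(axis=0) - padding
    hi = P.max(axis=0) + padding
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate bounding box (zero extent)")
    axes = []
    for n, a, b in zip((nx, ny, nz), lo, hi):
        if mode == "centers":
            step = (b - a) / n
            axes.append(a + step * (np.arange(n) + 0.5))
        elif mode == "corners":
            axes.append(np.linspace(a, b, n) if n > 1 else np.array([(a + b) / 2]))
        else:
            raise ValueError(f"unknown grid mode {mode!r}")
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def select_seeds(
    candidates: np.ndarray,
    protein_coords: np.ndarray,
    n_seeds: int = 30,
    min_clash_dist: float = 3.0,
    seed: int = 0,
) -> SeedSet:
    """Clash-filter candidates and keep the n most solvent-exposed.

    Deterministic given the seed: survivors are ordered by decreasing
    distance to the nearest protein atom, ties broken by a seeded
    permutation of the candidate order.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    tree = cKDTree(np.atleast_2d(np.asarray(protein_coords, dtype=float)))
    dist, _ = tree.query(cand)
    keep = np.where(dist >= min_clash_dist)[0]
    if keep.size < n_seeds:
        raise ValueError(
            f"only {keep.size} candidates survive the {min_clash_dist} Å clash "
            f"filter; {n_seeds} requested")
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(cand.shape[0])
    order = keep[np.lexsort((tiebreak[keep], -dist[keep]))]
    chosen = order[:n_seeds]
    return SeedSet(points=cand[chosen], grid_index=chosen,
                   min_protein_dist=dist[chosen])
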