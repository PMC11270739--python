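"""Unified ligand states (ULS): fingerprinting and cross-replicate
clustering of metastable states.

Metastable states estimated independently per replicate (and per seeding
scheme) are matched across runs by a geometric fingerprint: for each of
the five characteristic distances (ligand–catalytic machinery plus
ligand–bottleneck for each tunnel) the mean and the 25th, 50th and 75th
percentiles over the state's representative frames are collected into a
20-component vector.  The vectors are reduced to three principal
components and density-clustered (HDBSCAN, min_cluster_size=2); each
cluster is one unified ligand state, and points left as noise become
singleton ULSs.  A presence matrix then records, per ULS and replicate,
the mean stationary probability of its member states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

__all__ = [
    "StateEnsemble",
    "ULSAssignment",
    "state_fingerprint",
    "fingerprint_matrix",
    "reduce_fingerprints",
    "cluster_uls",
    "presence_matrix",
]

FINGERPRINT_STATS = ("mean", "p25", "p50", "p75")


@dataclass
class StateEnsemble:
    """Representative distance vectors of one metastable state.

    ``distances`` has one row per representative frame and one column per
    characteristic distance (d_cat first, then tunnels in canonical
    order).  ``probability`` is the state's stationary probability in its
    source MSM, when available.
    """

    state_id: str
    scheme: str
    replicate: str
    distances: np.ndarray               # (n_rep, 1 + n_tunnels)
    probability: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.atleast_2d(np.asarray(self.distances, dtype=float))
        if self.distances.shape[0] < 1:
            raise ValueError(f"state {self.state_id}: empty ensemble")
        if self.probability is not None and not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")


def state_fingerprint(ens: StateEnsemble) -> np.ndarray:
    """20-component fingerprint of one state ensemble.

    Order: for each distance column, (mean, p25, p50, p75).  Percentiles
    use linear interpolation between order statistics.
    """
    X = ens.distances
    if X.shape[0] == 0:
        raise ValueError("empty ensemble")
    parts = []
    for j in range(X.shape[1]):
        col = X[:, j]
        q = np.percentile(col, [25, 50, 75])
        parts.extend([col.mean(), q[0], q[1], q[2]])
    return np.asarray(parts, dtype=float)


def fingerprint_matrix(ensembles: Sequence[StateEnsemble]) -> pd.DataFrame:
    """Stack fingerprints into a table indexed by state id."""
    n_dist = ensembles[0].distances.shape[1]
    cols = [f"d{j}_{s}" for j in range(n_dist) for s in FINGERPRINT_STATS]
    rows = {e.state_id: state_fingerprint(e) for e in ensembles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def reduce_fingerprints(
    F: np.ndarray | pd.DataFrame,
    n_components: int = 3,
    standardize: bool = True,
) -> np.ndarray:
    """Project fingerprints onto their leading principal components.

    Columns are standardised (zero mean, unit variance; zero-variance
    columns left centred) by default — the 20 variables share units but
    differ widely in spread.  The sign of each component is fixed so that
    its largest-magnitude loading is positive.
    """
    X = np.asarray(F, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 states to reduce")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] *= -1.0
    return scores


@dataclass
class ULSAssignment:
    """Map metastable state -> ULS label.

    Cluster labels are ``ULS1, ULS2, ...`` ordered by decreasing cluster
    size (ties by first-member order); noise points get unique singleton
    labels ``ULS<k>`` continuing the numbering.
    """

    labels: dict[str, str]              # state_id -> ULS label
    uls_ids: tuple[str, ...]            # all labels in canonical order

    def members(self, uls: str) -> list[str]:
        return [s for s, u in self.labels.items() if u == uls]


def cluster_uls(
    scores: np.ndarray,
    state_ids: Sequence[str],
    min_cluster_size: int = 2,
) -> ULSAssignment:
    """Density-cluster PCA scores into unified ligand states.

    HDBSCAN with the given ``min_cluster_size`` (all other parameters at
    their defaults); noise points become singleton ULSs.  Degenerate
    inputs (fewer points than ``min_cluster_size``, or all points
    coincident) are handled explicitly.
    """
    X = np.asarray(scores, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("scores must be finite")
    n = X.shape[0]
    if len(state_ids) != n:
        raise ValueError("state_ids must match scores rows")

    if n < max(min_cluster_size, 2):
        raw = np.full(n, -1)
    elif np.allclose(X, X[0], atol=1e-12):
        raw = np.zeros(n, dtype=int)
    else:
        raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(X)
        if (raw == -1).all():
            # a lone dense group plus outliers: the default tree refuses a
            # single root cluster, so allow one before declaring all noise
            raw = HDBSCAN(min_cluster_size=min_cluster_size, copy=True,
                          allow_single_cluster=True).fit_predict(X)

    # renumber: clusters by (size desc, first-member order), then singletons
    order: list[tuple[int, ...]] = []
    for c in sorted(set(raw) - {-1}):
        members = np.where(raw == c)[0]
        order.append((-len(members), int(members[0]), c))
    order.sort()
    labels: dict[str, str] = {}
    next_id = 1
    for _, _, c in order:
        for i in np.where(raw == c)[0]:
            labels[state_ids[i]] = f"ULS{next_id}"
        next_id += 1
    for i in np.where(raw == -1)[0]:
        labels[state_ids[i]] = f"ULS{next_id}"
        next_id += 1
    uls_ids = tuple(f"ULS{k}" for k in range(1, next_id))
    # preserve input order of state ids in the mapping
    labels = {sid: labels[sid] for sid in state_ids}
    return ULSAssignment(labels, uls_ids)


def presence_matrix(
    assign: ULSAssignment,
    ensembles: Sequence[StateEnsemble],
) -> pd.DataFrame:
    """ULS × (scheme, replicate) table of mean member-state probabilities.

    A cell holds the mean stationary probability of the ULS's member
    states in that replicate (NaN where the ULS is absent).  When no
    ensemble carries probabilities the cells hold membership counts
    instead.
    """
    by_id = {e.state_id: e for e in ensembles}
    have_probs = any(e.probability is not None for e in ensembles)
    cells: dict[tuple[str, str], dict[str, list[float]]] = {}
    for sid, uls in assign.labels.items():
        e = by_id[sid]
        col = (e.scheme, e.replicate)
        val = e.probability if (have_probs and e.probability is not None) else 1.0
        cells.setdefault(col, {}).setdefault(uls, []).append(float(val))
    columns = sorted(cells)
    data = {}
    for col in columns:
        col_vals = {}
        for uls in assign.uls_ids:
            vals = cells[col].get(uls)
            if vals is None:
                col_vals[uls] = np.nan
            else:
                col_vals[uls] = float(np.mean(vals)) if have_probs else float(len(vals))
        data[col] = col_vals
    out = pd.DataFrame(data, index=list(assign.uls_ids))
    if columns:
        out.columns = pd.MultiIndex.from_tuples(columns, names=["scheme", "replicate"])
    return out
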