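"""Markov-state-model kinetics: TICA, microstate clustering, transition
matrices, validation, metastable lumping, MFPTs and binding rates.

The stage mirrors standard MSM practice: distance features are projected
onto their slowest linear subspace with time-lagged independent component
analysis (TICA), discretised into microstates by (mini-batch) k-means,
and transitions are counted at a lag time τ with a sliding window.  The
row-stochastic transition matrix P(τ) yields implied timescales
t_i = −τ/ln λ_i, metastable macrostates via spectral lumping (k-means on
the leading right eigenvectors), and mean first-passage times between a
bulk-like source set and a bound sink set.  Association and dissociation
rates are reciprocal MFPTs and their ratio k_off/k_on is the equilibrium
dissociation constant (reported as the dimensionless MFPT ratio; any
volume/standard-state conversion is left to the caller).

Markovianity is checked with the Chapman–Kolmogorov test: the
macrostate self-transition probabilities predicted by propagating the
model, (P(τ))^k, are compared with those re-estimated directly at lag kτ,
with a bootstrap confidence band over trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans, MiniBatchKMeans

__all__ = [
    "TICAResult",
    "MSMModel",
    "KineticEstimates",
    "tica",
    "cluster_microstates",
    "count_matrix",
    "largest_connected_set",
    "transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "ck_test",
    "lump_metastable",
    "mfpt",
    "rates_and_kd",
    "estimate_msm",
]


# ---------------------------------------------------------------- TICA

@dataclass
class TICAResult:
    coords: np.ndarray          # (n_frames, n_dims) projected coordinates
    eigenvalues: np.ndarray     # autocorrelations of the components, desc
    components: np.ndarray      # (n_features, n_dims) projection vectors
    lag: int
    mean: np.ndarray


def tica(
    X: np.ndarray,
    lag: int,
    n_dims: int = 3,
    ridge: float = 1e-6,
) -> TICAResult:
    """Time-lagged independent component analysis (symmetrised estimator).

    Solves the generalised eigenproblem C(τ) v = λ C(0) v with the
    symmetrised lagged covariance; components are ordered by decreasing
    eigenvalue (autocorrelation at the lag).  A small ridge on C(0) keeps
    the problem well conditioned; signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be (n_frames, n_features)")
    n, d = X.shape
    if lag < 1 or n <= lag:
        raise ValueError("need n_frames > lag >= 1")
    n_dims = min(n_dims, d)
    mean = X.mean(axis=0)
    Xc = X - mean
    X0, Xt = Xc[:-lag], Xc[lag:]
    m = X0.shape[0]
    C0 = (X0.T @ X0 + Xt.T @ Xt) / (2.0 * m)
    Ct = (X0.T @ Xt + Xt.T @ X0) / (2.0 * m)
    C0r = C0 + ridge * np.eye(d)
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0r)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular instantaneous covariance; increase the ridge parameter"
        ) from err
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order][:n_dims], evecs[:, order][:, :n_dims]
    for k in range(n_dims):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            evecs[:, k] = -v
    return TICAResult(Xc @ evecs, evals, evecs, lag, mean)


# ---------------------------------------------------- discretisation

def cluster_microstates(
    coords: np.ndarray,
    k: int,
    seed: int = 0,
    minibatch: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster projected coordinates into k microstates.

    Returns (assignments, cluster centers).  A fixed seed gives identical
    assignments across calls.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] and coords.ndim == 2 and coords.shape[1] == 0:
        raise ValueError("coords must have at least one column")
    n_unique = np.unique(coords, axis=0).shape[0]
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds number of points {coords.shape[0]}")
    k_eff = min(k, n_unique)
    cls = (MiniBatchKMeans if minibatch else KMeans)(
        n_clusters=k_eff, random_state=seed, n_init=3)
    labels = cls.fit_predict(coords)
    return labels.astype(int), cls.cluster_centers_


# ------------------------------------------------- transition matrices

def count_matrix(
    dtrajs: Sequence[np.ndarray] | np.ndarray,
    lag: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition count matrix at the given lag (frames).

    ``C[i, j]`` counts pairs (t, t+lag) with state i then j.  Multiple
    trajectories are never concatenated: no pair spans a boundary.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    trajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) + 1 for d in trajs if d.size), default=0)
    C = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    for d in trajs:
        if d.size > lag:
            any_pairs = True
            np.add.at(C, (d[:-lag], d[lag:]), 1)
    if not any_pairs:
        raise ValueError("no transition pairs: lag >= length of every trajectory")
    return C


def largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph."""
    n_comp, labels = connected_components(C > 0, directed=True, connection="strong")
    sizes = np.bincount(labels, weights=C.sum(axis=1) + C.sum(axis=0), minlength=n_comp)
    # prefer the component carrying the most counts; ties by size then index
    best = int(np.argmax(sizes))
    return np.where(labels == best)[0]


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalised."""
    evals, evecs = scipy.linalg.eig(P.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix(
    C: np.ndarray,
    reversible: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate P (row-stochastic) and π from a count matrix.

    The estimate is restricted to the largest strongly connected set;
    returns ``(P, pi, active)`` where ``active`` maps rows of P back to
    the original state indices.  Reversible mode symmetrises the counts,
    (C + Cᵀ)/2, before row-normalising, which enforces detailed balance;
    non-reversible mode is the per-row maximum-likelihood estimate.
    """
    C = np.asarray(C, dtype=float)
    active = largest_connected_set(C)
    if active.size == 0:
        raise ValueError("empty connected set")
    Ca = C[np.ix_(active, active)]
    if reversible:
        Ca = 0.5 * (Ca + Ca.T)
    rows = Ca.sum(axis=1)
    if (rows == 0).any():
        raise ValueError("state without outgoing counts inside connected set")
    P = Ca / rows[:, None]
    if reversible:
        pi = rows / rows.sum()     # symmetric counts: row sums are stationary
    else:
        pi = stationary_distribution(P)
    return P, pi, active


# ------------------------------------------------------- validation

def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    frame_interval: float = 1.0,
    n_timescales: int = 5,
    reversible: bool = True,
) -> pd.DataFrame:
    """Implied timescales t_i(τ) = −τ/ln λ_i(τ) across candidate lags.

    Times are reported in the unit of ``frame_interval`` × frames (ps if
    the interval is in ps).  Complex eigenvalues are reported by modulus
    with a warning.  Lag-independence of the t_i indicates Markovianity.
    """
    lags = list(lags)
    if len(lags) < 2:
        raise ValueError("need at least 2 lags")
    rows = []
    for lag in lags:
        P, _, _ = transition_matrix(count_matrix(dtrajs, lag), reversible=reversible)
        evals = np.linalg.eigvals(P)
        if np.abs(evals.imag).max() > 1e-10:
            warnings.warn("complex transition-matrix eigenvalues; using moduli")
        mags = np.sort(np.abs(evals))[::-1]
        rec: dict[str, float] = {"lag": lag}
        j = 0
        for lam in mags:
            if lam >= 1.0 - 1e-12:   # stationary eigenvalue(s) excluded
                continue
            if j >= n_timescales or lam <= 0:
                break
            rec[f"t{j + 2}"] = -lag * frame_interval / np.log(lam)
            j += 1
        rows.append(rec)
    return pd.DataFrame(rows).set_index("lag")


def _macro_self_probs(P: np.ndarray, pi: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    """π-weighted probability of remaining in each macrostate under P."""
    out = np.empty(len(sets))
    for a, members in enumerate(sets):
        w = pi[members]
        out[a] = float(w @ P[np.ix_(members, members)].sum(axis=1) / w.sum())
    return out


def ck_test(
    dtrajs: Sequence[np.ndarray],
    lag: int,
    factors: Sequence[int] = (2, 3, 4),
    n_macrostates: int = 2,
    n_boot: int = 100,
    seed: int = 0,
    reversible: bool = True,
) -> pd.DataFrame:
    """Chapman–Kolmogorov test on macrostate self-transition probabilities.

    For each factor k, compares the model prediction (P(τ))^k, aggregated
    onto macrostates, against the estimate re-computed at lag kτ.  The
    95% confidence band comes from bootstrap resampling of whole
    trajectories.  Rows report (factor, macrostate, predicted, estimated,
    absolute deviation, band, within_band).
    """
    trajs = [np.asarray(d, dtype=int) for d in dtrajs]
    rng = np.random.default_rng(seed)
    C = count_matrix(trajs, lag)
    P, pi, active = transition_matrix(C, reversible=reversible)
    lump = lump_metastable(P, n_macrostates, pi=pi, seed=seed)
    sets_active = [np.where(lump == a)[0] for a in range(n_macrostates)]
    full_sets = [active[s] for s in sets_active]

    def estimate_at(trs: list[np.ndarray], klag: int) -> np.ndarray | None:
        try:
            Ck = count_matrix(trs, klag, n_states=C.shape[0])
        except ValueError:
            return None
        sub = Ck[np.ix_(active, active)]
        if reversible:
            sub = 0.5 * (sub + sub.T)
        rows = sub.sum(axis=1)
        if (rows == 0).any():
            return None
        Pk = sub / rows[:, None]
        pik = rows / rows.sum() if reversible else stationary_distribution(Pk)
        return _macro_self_probs(Pk, pik, sets_active)

    records = []
    for k in factors:
        pred = _macro_self_probs(np.linalg.matrix_power(P, k), pi, sets_active)
        est = estimate_at(trajs, k * lag)
        if est is None:
            warnings.warn(f"factor {k}: insufficient pairs at lag {k * lag}; skipped")
            continue
        boots = []
        for _ in range(n_boot):
            sample = [trajs[i] for i in rng.integers(0, len(trajs), len(trajs))]
            b = estimate_at(sample, k * lag)
            if b is not None:
                boots.append(b)
        B = np.array(boots) if boots else est[None, :]
        lo = np.percentile(B, 2.5, axis=0)
        hi = np.percentile(B, 97.5, axis=0)
        for a in range(n_macrostates):
            records.append({
                "factor": k, "macrostate": a,
                "predicted": pred[a], "estimated": est[a],
                "deviation": abs(pred[a] - est[a]),
                "band_lo": lo[a], "band_hi": hi[a],
                "within_band": bool(lo[a] <= pred[a] <= hi[a]),
            })
    return pd.DataFrame(records)


# ------------------------------------------------------ lumping / MFPT

def lump_metastable(
    P: np.ndarray,
    n_states: int,
    pi: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Spectral lumping of microstates into metastable macrostates.

    K-means on the leading ``n_states`` right eigenvectors of P (real
    parts, π-weighted rows).  A simplification of PCCA++-style fuzzy
    membership: crisp assignments from the same invariant subspace.
    Labels are renumbered by first occurrence for determinism.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if not 2 <= n_states <= k:
        raise ValueError("need 2 <= n_states <= n_microstates")
    if n_states == k:
        return np.arange(k)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(np.abs(evals))[::-1]
    gap_support = np.sum(np.abs(evals) > 0.5)
    if n_states > max(gap_support, 2):
        warnings.warn("n_states exceeds the slow spectral support; lumping may be arbitrary")
    V = np.real(evecs[:, order[:n_states]])
    if pi is not None:
        V = V * np.sqrt(np.asarray(pi))[:, None]
    # scale columns to comparable magnitude before k-means
    norms = np.linalg.norm(V, axis=0)
    norms[norms == 0] = 1.0
    labels = KMeans(n_clusters=n_states, random_state=seed, n_init=10).fit_predict(V / norms)
    # renumber by first occurrence
    remap: dict[int, int] = {}
    out = np.empty(k, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def pick_n_metastable(P: np.ndarray, n_min: int = 2, n_max: int = 8) -> int:
    """Number of metastable states from the largest spectral gap.

    Heuristic: choose m maximising λ_m − λ_{m+1} over sorted eigenvalue
    moduli, within [n_min, n_max]."""
    mags = np.sort(np.abs(np.linalg.eigvals(P)))[::-1]
    n_max = min(n_max, mags.size - 1)
    if n_max < n_min:
        return max(2, min(mags.size, n_min))
    gaps = mags[n_min - 1:n_max] - mags[n_min:n_max + 1]
    return n_min + int(np.argmax(gaps))


def mfpt(
    P: np.ndarray,
    source: Sequence[int],
    sink: Sequence[int],
    lag_time: float = 1.0,
    pi: np.ndarray | None = None,
) -> float:
    """Mean first-passage time from a source set to a sink set.

    Solves m_i = 0 on the sink and m_i = τ + Σ_j P_ij m_j elsewhere, then
    returns the π-weighted average of m over the source (π restricted to
    the source and renormalised; uniform weights if π is omitted).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    source = np.asarray(sorted(set(int(i) for i in source)), dtype=int)
    sink = np.asarray(sorted(set(int(i) for i in sink)), dtype=int)
    if source.size == 0 or sink.size == 0:
        raise ValueError("source and sink must be non-empty")
    if np.intersect1d(source, sink).size:
        raise ValueError("source and sink must be disjoint")
    # reachability: every source state must reach the sink
    reach = np.zeros(n, dtype=bool)
    reach[sink] = True
    adj = P > 0
    for _ in range(n):
        new = reach | adj @ reach
        if (new == reach).all():
            break
        reach = new
    if not reach[source].all():
        raise ValueError("absorbing failure: sink unreachable from source")
    A = np.eye(n) - P
    b = np.full(n, float(lag_time))
    A[sink, :] = 0.0
    A[sink, sink] = 1.0
    b[sink] = 0.0
    m = np.linalg.solve(A, b)
    if pi is None:
        w = np.ones(source.size)
    else:
        w = np.asarray(pi, dtype=float)[source]
    w = w / w.sum()
    return float(w @ m[source])


@dataclass
class KineticEstimates:
    """Binding kinetics from MFPTs: k_on = 1/MFPT_on, k_off = 1/MFPT_off,
    and the dimensionless k_d = k_off/k_on = MFPT_on/MFPT_off."""

    mfpt_on: float
    mfpt_off: float
    k_on: float
    k_off: float
    k_d: float
    source: tuple[int, ...] = ()
    sink: tuple[int, ...] = ()


def rates_and_kd(
    mfpt_on: float,
    mfpt_off: float,
    source: Sequence[int] = (),
    sink: Sequence[int] = (),
) -> KineticEstimates:
    if not (np.isfinite(mfpt_on) and np.isfinite(mfpt_off)):
        raise ValueError("MFPTs must be finite")
    if mfpt_on <= 0 or mfpt_off <= 0:
        raise ValueError("MFPTs must be positive")
    k_on, k_off = 1.0 / mfpt_on, 1.0 / mfpt_off
    return KineticEstimates(mfpt_on, mfpt_off, k_on, k_off, k_off / k_on,
                            tuple(source), tuple(sink))


# -------------------------------------------------------- convenience

@dataclass
class MSMModel:
    """Bundled result of one MSM estimation."""

    dtrajs: list[np.ndarray]
    lag: int
    count_mat: np.ndarray
    P: np.ndarray
    pi: np.ndarray
    active: np.ndarray                      # active-set -> original microstate
    lumping: np.ndarray                     # per active microstate -> macrostate
    frame_interval: float = 1.0
    centers: np.ndarray | None = None
    tica_result: TICAResult | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_macrostates(self) -> int:
        return int(self.lumping.max()) + 1

    @property
    def lag_time(self) -> float:
        return self.lag * self.frame_interval

    def eigenvalues(self, n: int = 10) -> np.ndarray:
        mags = np.sort(np.abs(np.linalg.eigvals(self.P)))[::-1]
        return mags[:n]

    def macrostate_members(self, a: int) -> np.ndarray:
        """Active-set indices belonging to macrostate a."""
        return np.where(self.lumping == a)[0]

    def macrostate_probability(self, a: int) -> float:
        return float(self.pi[self.macrostate_members(a)].sum())


def estimate_msm(
    X: np.ndarray | Sequence[np.ndarray],
    tica_lag: int,
    msm_lag: int,
    n_microstates: int = 1000,
    n_metastable: int | None = None,
    n_tica_dims: int = 3,
    seed: int = 0,
    reversible: bool = True,
    frame_interval: float = 1.0,
) -> MSMModel:
    """Full featurised-data → MSM pipeline for one or more trajectories.

    TICA is fit on the pooled frames; clustering and counting respect
    trajectory boundaries.  ``n_metastable=None`` selects the macrostate
    count from the largest spectral gap.
    """
    blocks = [np.atleast_2d(np.asarray(x, dtype=float)) for x in
              ([X] if isinstance(X, np.ndarray) else list(X))]
    lengths = [b.shape[0] for b in blocks]
    pooled = np.vstack(blocks)
    tic = tica(pooled, lag=tica_lag, n_dims=n_tica_dims)
    k = min(n_microstates, np.unique(tic.coords, axis=0).shape[0])
    labels, centers = cluster_microstates(tic.coords, k, seed=seed)
    dtrajs, off = [], 0
    for ln in lengths:
        dtrajs.append(labels[off:off + ln])
        off += ln
    C = count_matrix(dtrajs, msm_lag, n_states=k)
    P, pi, active = transition_matrix(C, reversible=reversible)
    if n_metastable is None:
        n_metastable = pick_n_metastable(P)
    n_metastable = min(n_metastable, P.shape[0])
    if n_metastable >= 2 and P.shape[0] >= 2:
        lumping = lump_metastable(P, n_metastable, pi=pi, seed=seed)
    else:
        lumping = np.zeros(P.shape[0], dtype=int)
    return MSMModel(dtrajs, msm_lag, C, P, pi, active, lumping,
                    frame_interval=frame_interval, centers=centers,
                    tica_result=tic)
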