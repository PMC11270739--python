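"""Readers, writers, configuration and the end-to-end pipeline.

File formats are deliberately plain: multi-model PDB or a
``frame,atom_id,x,y,z`` table for coordinates, TSV for every derived
table (distance series, events, utilization, fingerprints, presence
matrix), YAML or JSON for configuration and run manifests, and a single
JSON report for a full pipeline run.  Every output embeds the
configuration echo so a run is reconstructible from its manifest and
seeds.  Logging goes to stderr; machine-readable output never mixes with
log text.
"""

from __future__ import annotations

import io as _io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import msm as msm_mod
from . import transit as transit_mod
from . import uls as uls_mod
from .geometry import (ELEMENT_MASSES, CoordinateTrajectory, DistanceSeries,
                       TunnelNetwork, build_distance_series, classify_region,
                       epoch_region_fractions, region_fractions)
from .transit import TransitParams

logger = logging.getLogger("tunneltransit")

__all__ = [
    "Config",
    "RunEntry",
    "RunManifest",
    "load_config",
    "read_trajectory",
    "write_trajectory",
    "read_distance_series",
    "write_distance_series",
    "load_manifest",
    "run_pipeline",
]

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


# ----------------------------------------------------------- config

@dataclass
class Config:
    """All cutoffs and stage parameters in one place.

    Defaults are the values of the study this pipeline reproduces:
    regions 5/19 Å, band cutoffs 2/5 Å with 1 Å tolerance, TICA lag
    2 ns, MSM lag 20 ns, 1000 microstates, HDBSCAN min_cluster_size 2.
    """

    network: TunnelNetwork | None = None
    ligand: tuple[str, ...] = ("LIG",)
    r_cavity: float = 5.0
    r_bulk: float = 19.0
    bt_cutoff_along: float = 2.0
    bt_cutoff_across: float = 5.0
    dist_tolerance: float = 1.0
    tica_lag_ns: float = 2.0
    msm_lag_ns: float = 20.0
    n_microstates: int = 1000
    n_metastable: int | None = None         # None = spectral-gap heuristic
    n_tica_dims: int = 3
    min_cluster_size: int = 2
    n_representatives: int = 1000
    com_weights: str | None = None          # None = mass if available
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_cavity < self.r_bulk:
            raise ValueError("need 0 < r_cavity < r_bulk")

    @property
    def transit_params(self) -> TransitParams:
        return TransitParams(self.bt_cutoff_along, self.bt_cutoff_across,
                             self.dist_tolerance)

    def lag_frames(self, lag_ns: float, frame_interval_ps: float) -> int:
        return max(1, int(round(lag_ns * 1000.0 / frame_interval_ps)))

    def echo(self) -> dict:
        d = {
            "ligand": list(self.ligand),
            "cutoffs": {
                "r_cavity": self.r_cavity, "r_bulk": self.r_bulk,
                "bt_cutoff_along": self.bt_cutoff_along,
                "bt_cutoff_across": self.bt_cutoff_across,
                "dist_tolerance": self.dist_tolerance,
            },
            "lags_ns": {"tica": self.tica_lag_ns, "msm": self.msm_lag_ns},
            "msm": {"n_microstates": self.n_microstates,
                    "n_metastable": self.n_metastable,
                    "n_tica_dims": self.n_tica_dims},
            "uls": {"min_cluster_size": self.min_cluster_size,
                    "n_representatives": self.n_representatives},
            "seed": self.seed,
        }
        if self.network is not None:
            d["catalytic"] = list(self.network.catalytic)
            d["tunnels"] = {t: list(g) for t, g in self.network.tunnels.items()}
        return d


def load_config(path: str | Path) -> Config:
    """Load a YAML/JSON configuration file.

    Recognised keys: ``catalytic``, ``tunnels``, ``ligand``, ``cutoffs``
    (r_cavity, r_bulk, bt_cutoff_along, bt_cutoff_across, dist_tolerance),
    ``lags_ns`` (tica, msm), ``msm`` (n_microstates, n_metastable,
    n_tica_dims), ``uls`` (min_cluster_size), ``seed``.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping")
    kw: dict = {}
    if "catalytic" in raw or "tunnels" in raw:
        if not ("catalytic" in raw and "tunnels" in raw):
            raise ValueError("config must define both catalytic and tunnels (or neither)")
        kw["network"] = TunnelNetwork(raw["catalytic"], raw["tunnels"])
    if "ligand" in raw:
        lig = raw["ligand"]
        kw["ligand"] = tuple([lig] if isinstance(lig, str) else lig)
    cut = raw.get("cutoffs", {})
    for k in ("r_cavity", "r_bulk", "bt_cutoff_along", "bt_cutoff_across",
              "dist_tolerance"):
        if k in cut:
            kw[k] = float(cut[k])
    lags = raw.get("lags_ns", {})
    if "tica" in lags:
        kw["tica_lag_ns"] = float(lags["tica"])
    if "msm" in lags:
        kw["msm_lag_ns"] = float(lags["msm"])
    m = raw.get("msm", {})
    for k in ("n_microstates", "n_tica_dims"):
        if k in m:
            kw[k] = int(m[k])
    if "n_metastable" in m:
        v = m["n_metastable"]
        kw["n_metastable"] = None if v in (None, "auto") else int(v)
    u = raw.get("uls", {})
    if "min_cluster_size" in u:
        kw["min_cluster_size"] = int(u["min_cluster_size"])
    if "n_representatives" in u:
        kw["n_representatives"] = int(u["n_representatives"])
    if "seed" in raw:
        kw["seed"] = int(raw["seed"])
    return Config(**kw)


# ----------------------------------------------------- trajectory I/O

def _tag_to_pdb(tag: str, fallback_id: int) -> tuple[str, int]:
    """Residue tag -> (res_name, res_id) for PDB output."""
    m = re.match(r"^([A-Za-z]+?)(\d+)$", tag)
    if m:
        name, num = m.group(1), int(m.group(2))
        if len(name) == 1 and name.upper() in AA_1TO3:
            return AA_1TO3[name.upper()], num
        if len(name) <= 3:
            return name.upper(), num
    return tag[:3].upper(), fallback_id


def write_trajectory(traj: CoordinateTrajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    tags = traj.residue_tags()
    res_ids: dict[str, tuple[str, int]] = {}
    next_fallback = 1
    for tag in tags:
        if tag not in res_ids:
            res_ids[tag] = _tag_to_pdb(tag, next_fallback)
            next_fallback += 1
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for a, aid in enumerate(traj.atom_ids):
            tag = tags[a]
            atom_name = aid.split("/", 1)[1] if "/" in aid else "X"
            res_name, res_id = res_ids[tag]
            x, y, z = traj.coords[f, a]
            elem = re.sub(r"\d", "", atom_name)[:2].upper() or "C"
            if elem not in ELEMENT_MASSES:
                elem = elem[0] if elem and elem[0] in ELEMENT_MASSES else "C"
            lines.append(
                f"ATOM  {a + 1:5d} {atom_name:<4.4s}{res_name:>4.3s} A{res_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {elem:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_pdb(path: Path, frame_interval: float) -> CoordinateTrajectory:
    import biotite.structure.io.pdb as pdbio

    pdb = pdbio.PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.atleast_3d(stack.coord)
    if coords.ndim == 2:   # single model
        coords = coords[None]
    res_names = stack.res_name
    res_id_arr = stack.res_id
    atom_names = stack.atom_name
    elements = stack.element
    # residue names that occur with a single res_id keep a bare tag
    name_ids: dict[str, set[int]] = {}
    for rn, ri in zip(res_names, res_id_arr):
        name_ids.setdefault(rn, set()).add(int(ri))
    atom_ids, masses = [], []
    for rn, ri, an, el in zip(res_names, res_id_arr, atom_names, elements):
        if rn in AA_3TO1:
            tag = f"{AA_3TO1[rn]}{int(ri)}"
        elif len(name_ids[rn]) == 1:
            tag = rn
        else:
            tag = f"{rn}{int(ri)}"
        atom_ids.append(f"{tag}/{an}")
        masses.append(ELEMENT_MASSES.get(str(el).upper(), 12.011))
    return CoordinateTrajectory(coords, atom_ids, masses=np.asarray(masses),
                                frame_interval=frame_interval)


def _read_table(path: Path, frame_interval: float) -> CoordinateTrajectory:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"frame", "atom_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"coordinate table needs columns {sorted(required)}")
    if df["frame"].isna().any():
        raise ValueError("coordinate table has a missing frame index")
    frames = sorted(df["frame"].unique())
    first = None
    blocks = []
    for fi, fr in enumerate(frames):
        block = df[df["frame"] == fr]
        atoms = list(block["atom_id"])
        if first is None:
            first = atoms
        elif atoms != first:
            raise ValueError(f"inconsistent atom set at frame {fr}")
        blocks.append(block[["x", "y", "z"]].to_numpy(dtype=float))
    return CoordinateTrajectory(np.stack(blocks), list(first),
                                frame_interval=frame_interval)


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    frame_interval: float = 100.0,
) -> CoordinateTrajectory:
    """Read a multi-model PDB or a ``frame,atom_id,x,y,z`` table."""
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "table"
    if fmt == "pdb":
        return _read_pdb(path, frame_interval)
    if fmt == "table":
        return _read_table(path, frame_interval)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_table(traj: CoordinateTrajectory, path: str | Path) -> None:
    rows = []
    for f in range(traj.n_frames):
        for a, aid in enumerate(traj.atom_ids):
            x, y, z = traj.coords[f, a]
            rows.append((f, aid, x, y, z))
    pd.DataFrame(rows, columns=["frame", "atom_id", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


# ------------------------------------------------ distance series I/O

def write_distance_series(ds: DistanceSeries, path: str | Path) -> None:
    """TSV with columns frame, d_cat, d_bt_<T>..., L_<T>...; metadata and
    frame_interval as ``# key=value`` header comments.  Values at 6
    decimals (round-trip exact at that precision)."""
    buf = _io.StringIO()
    buf.write(f"# frame_interval={ds.frame_interval:g}\n")
    for k, v in sorted(ds.metadata.items()):
        buf.write(f"# {k}={v}\n")
    cols = {"frame": np.arange(ds.n_frames), "d_cat": ds.d_cat}
    for t in ds.tunnel_ids:
        cols[f"d_bt_{t}"] = ds.d_bt[t]
    for t in ds.tunnel_ids:
        cols[f"L_{t}"] = ds.L[t]
    pd.DataFrame(cols).to_csv(buf, sep="\t", index=False, float_format="%.6f")
    Path(path).write_text(buf.getvalue())


def read_distance_series(path: str | Path) -> DistanceSeries:
    meta: dict = {}
    frame_interval = 100.0
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line.lstrip("# ").partition("=")
        if key == "frame_interval":
            frame_interval = float(val)
        else:
            meta[key] = val
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t")
    tunnels = [c[len("d_bt_"):] for c in df.columns if c.startswith("d_bt_")]
    d_bt = {t: df[f"d_bt_{t}"].to_numpy() for t in tunnels}
    L = {t: df[f"L_{t}"].to_numpy() for t in tunnels}
    return DistanceSeries(df["d_cat"].to_numpy(), d_bt, L,
                          frame_interval=frame_interval, metadata=meta)


# ------------------------------------------------------- run manifest

@dataclass
class RunEntry:
    run_id: str
    path: Path
    scheme: str = "default"
    replicate: str = "r1"
    epoch: int | None = None
    kind: str = "distances"        # distances | pdb | table

    def metadata(self) -> dict:
        md = {"run_id": self.run_id, "scheme": self.scheme,
              "replicate": self.replicate}
        if self.epoch is not None:
            md["epoch"] = self.epoch
        return md


@dataclass
class RunManifest:
    runs: list[RunEntry]
    frame_interval: float = 100.0

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty manifest")
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("run ids must be unique")
        for r in self.runs:
            if not Path(r.path).exists():
                raise FileNotFoundError(f"run {r.run_id}: missing file {r.path}")


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "runs" not in raw:
        raise ValueError("manifest must be a mapping with a 'runs' list")
    runs = []
    for rec in raw["runs"]:
        p = Path(rec["path"])
        if not p.is_absolute():
            p = path.parent / p
        runs.append(RunEntry(
            run_id=str(rec["run_id"]), path=p,
            scheme=str(rec.get("scheme", "default")),
            replicate=str(rec.get("replicate", "r1")),
            epoch=rec.get("epoch"),
            kind=str(rec.get("kind", "distances"))))
    return RunManifest(runs, frame_interval=float(raw.get("frame_interval", 100.0)))


# ----------------------------------------------------------- pipeline

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj


def _load_series(entry: RunEntry, cfg: Config, frame_interval: float) -> DistanceSeries:
    if entry.kind == "distances":
        ds = read_distance_series(entry.path)
    else:
        if cfg.network is None:
            raise ValueError("coordinate input requires a tunnel network in the config")
        traj = read_trajectory(entry.path, fmt=entry.kind,
                               frame_interval=frame_interval)
        ds = build_distance_series(traj, cfg.network, ligand=cfg.ligand,
                                   weights=cfg.com_weights)
    ds.metadata.update(entry.metadata())
    return ds


def _auto_source_sink(model: msm_mod.MSMModel, d_cat_by_frame: np.ndarray,
                      cfg: Config) -> tuple[list[int], list[int]]:
    """Sink = macrostate most prevalent in the cavity; source = macrostates
    predominantly in bulk (fallback: farthest median)."""
    dtraj_all = np.concatenate(model.dtrajs)
    micro_of_active = {m: i for i, m in enumerate(model.active)}
    frac_cavity = np.zeros(model.n_macrostates)
    frac_bulk = np.zeros(model.n_macrostates)
    med = np.full(model.n_macrostates, np.nan)
    for a in range(model.n_macrostates):
        micros = set(model.active[model.macrostate_members(a)])
        mask = np.isin(dtraj_all, list(micros))
        if not mask.any():
            continue
        d = d_cat_by_frame[mask]
        frac_cavity[a] = float((d <= cfg.r_cavity).mean())
        frac_bulk[a] = float((d > cfg.r_bulk).mean())
        med[a] = float(np.median(d))
    sink_macro = int(np.argmax(frac_cavity)) if frac_cavity.max() > 0 \
        else int(np.nanargmin(med))
    source_macros = [a for a in range(model.n_macrostates)
                     if a != sink_macro and frac_bulk[a] > 0.5]
    if not source_macros:
        cand = [a for a in range(model.n_macrostates) if a != sink_macro]
        source_macros = [max(cand, key=lambda a: (med[a] if np.isfinite(med[a]) else -1))]
    sink = [int(i) for i in model.macrostate_members(sink_macro)]
    source = [int(i) for a in source_macros for i in model.macrostate_members(a)]
    return source, sink


def run_pipeline(
    manifest: RunManifest,
    cfg: Config,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute the full pipeline: distances → regions + transits → MSM →
    ULS → JSON summary.  Deterministic given the config seed."""
    seed = cfg.seed if seed is None else seed
    summary: dict = {"config": cfg.echo(), "seed": seed}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("distances")
    series: list[DistanceSeries] = []
    for entry in manifest.runs:
        try:
            series.append(_load_series(entry, cfg, manifest.frame_interval))
        except Exception as err:
            raise RuntimeError(f"stage distances, run {entry.run_id}: {err}") from err

    stage("regions")
    regions = {}
    for ds in series:
        labels = classify_region(ds, cfg.r_cavity, cfg.r_bulk)
        regions[ds.metadata["run_id"]] = region_fractions(labels)
    summary["region_fractions"] = regions
    if all("epoch" in ds.metadata for ds in series):
        summary["epoch_region_fractions"] = _jsonable(
            epoch_region_fractions(series, cfg.r_cavity, cfg.r_bulk).reset_index())

    stage("transit")
    categories = None
    if cfg.network is not None:
        categories = tuple(cfg.network.tunnel_ids) + (transit_mod.MIXED,
                                                      transit_mod.UNKNOWN)
    all_events = []
    for ds in series:
        try:
            all_events.extend(transit_mod.track_transits(ds, cfg.transit_params))
        except Exception as err:
            raise RuntimeError(
                f"stage transit, run {ds.metadata['run_id']}: {err}") from err
    util = transit_mod.count_utilization(all_events, categories)
    summary["n_events"] = len(all_events)
    summary["utilization"] = {
        "per_replicate": _jsonable(util.per_replicate.reset_index())
        if len(util.per_replicate) else None,
        "per_scheme": _jsonable(util.per_scheme.reset_index())
        if len(util.per_scheme) else None,
    }

    stage("msm")
    groups: dict[tuple[str, str], list[DistanceSeries]] = {}
    for ds in series:
        groups.setdefault((ds.metadata["scheme"], ds.metadata["replicate"]), []).append(ds)
    msm_reports = {}
    ensembles: list[uls_mod.StateEnsemble] = []
    rng = np.random.default_rng(seed)
    for (scheme, rep), group in sorted(groups.items()):
        feats = [ds.features() for ds in group]
        fi = group[0].frame_interval
        min_len = min(f.shape[0] for f in feats)
        tica_lag = min(cfg.lag_frames(cfg.tica_lag_ns, fi), max(1, min_len // 4))
        msm_lag = min(cfg.lag_frames(cfg.msm_lag_ns, fi), max(1, min_len // 4))
        n_micro = min(cfg.n_microstates, max(2, sum(f.shape[0] for f in feats) // 10))
        try:
            model = msm_mod.estimate_msm(
                feats, tica_lag=tica_lag, msm_lag=msm_lag,
                n_microstates=n_micro, n_metastable=cfg.n_metastable,
                n_tica_dims=min(cfg.n_tica_dims, feats[0].shape[1]),
                seed=seed, frame_interval=fi)
        except Exception as err:
            raise RuntimeError(f"stage msm, replicate {scheme}/{rep}: {err}") from err
        pooled = np.vstack(feats)
        dtraj_all = np.concatenate(model.dtrajs)
        d_cat_all = pooled[:, 0]
        report: dict = {
            "n_microstates": int(model.P.shape[0]),
            "n_metastable": model.n_macrostates,
            "lag_frames": model.lag,
            "lag_ns": model.lag * fi / 1000.0,
            "eigenvalues": model.eigenvalues(5),
            "stationary_entropy": float(-np.sum(model.pi * np.log(model.pi + 1e-300))),
        }
        # per-macrostate representative ensembles for the ULS stage
        for a in range(model.n_macrostates):
            micros = set(model.active[model.macrostate_members(a)])
            idx = np.where(np.isin(dtraj_all, list(micros)))[0]
            if idx.size == 0:
                continue
            take = rng.choice(idx, size=min(cfg.n_representatives, idx.size),
                              replace=False)
            ensembles.append(uls_mod.StateEnsemble(
                state_id=f"{scheme}-{rep}-m{a}", scheme=scheme, replicate=rep,
                distances=pooled[np.sort(take)],
                probability=model.macrostate_probability(a)))
        # kinetics when both ends of the binding process are represented
        if model.n_macrostates >= 2:
            try:
                source, sink = _auto_source_sink(model, d_cat_all, cfg)
                tau_ps = model.lag * fi
                m_on = msm_mod.mfpt(model.P, source, sink, lag_time=tau_ps, pi=model.pi)
                m_off = msm_mod.mfpt(model.P, sink, source, lag_time=tau_ps, pi=model.pi)
                kin = msm_mod.rates_and_kd(m_on, m_off, source, sink)
                report["kinetics"] = {
                    "mfpt_on_ns": kin.mfpt_on / 1000.0,
                    "mfpt_off_ns": kin.mfpt_off / 1000.0,
                    "k_on_per_ns": kin.k_on * 1000.0,
                    "k_off_per_ns": kin.k_off * 1000.0,
                    "k_d": kin.k_d,
                }
            except ValueError as err:
                report["kinetics"] = {"error": str(err)}
        msm_reports[f"{scheme}/{rep}"] = report
    summary["msm"] = msm_reports

    stage("uls")
    if len(ensembles) >= 2:
        F = uls_mod.fingerprint_matrix(ensembles)
        scores = uls_mod.reduce_fingerprints(F.to_numpy())
        assign = uls_mod.cluster_uls(scores, list(F.index),
                                     min_cluster_size=cfg.min_cluster_size)
        pres = uls_mod.presence_matrix(assign, ensembles)
        pres_flat = pres.copy()
        pres_flat.columns = ["/".join(c) for c in pres.columns]
        summary["uls"] = {
            "labels": assign.labels,
            "n_uls": len(assign.uls_ids),
            "presence": _jsonable(pres_flat.reset_index(names="uls")),
        }
    else:
        summary["uls"] = None

    summary = _jsonable(summary)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        ev_df = transit_mod.events_to_frame(all_events)
        ev_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
        if len(util.per_replicate):
            util.per_replicate.to_csv(outdir / "utilization_replicates.tsv", sep="\t")
        if len(util.per_scheme):
            util.per_scheme.to_csv(outdir / "utilization_schemes.tsv", sep="\t")
    return summary
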