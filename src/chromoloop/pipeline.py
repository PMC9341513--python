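"""End-to-end pipeline: build -> lift -> annotate -> simulate -> observe.

The pipeline config is a YAML document::

    name: mylocus
    tracks:
      dhs: dhs.bed
      ctcf: ctcf.bed
      states: states.bed
    build: build.txt            # chrom start end strand rows
    state_rules:                # state label -> model category
      Open: active_open
      Het: het
    score_normalization: max    # or "unit" for fixture tracks
    params:                     # SimulationParams overrides
      n_snapshots: 200
    observables:
      bin_size: 10000
      viewpoints: ["35000-36000"]
      probes: ["20000-60000"]
      promoters: [{tss: 30000, strand: "+"}]
      enhancer_states: ["Enh"]
    outdir: out/
    seed: 1

One master seed governs every stochastic stage through a stage-name-keyed
derivation (sha256 of "seed:stage"), so stages can be rerun independently
yet reproducibly. Every stage writes into its own subdirectory and the run
manifest records seeds, parameter values and content checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .annotate import annotate_beads
from .build import read_build_spec, lift_track
from .engine import run_simulation, Ensemble
from .intervals import read_bed, write_bed
from .observables import (
    contact_map,
    virtual_4c,
    insulation_and_boundaries,
    geometry_over_ensemble,
    bound_fraction,
    enhancer_contact_fraction,
    promoter_interval,
)
from .params import SimulationParams

__all__ = ["run_pipeline", "validate_config", "derive_seed", "load_config"]

_REQUIRED_KEYS = ("tracks", "build", "state_rules", "outdir")
_KNOWN_KEYS = _REQUIRED_KEYS + (
    "name", "params", "observables", "seed", "score_normalization",
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage-keyed seed derivation (stable across runs and platforms)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("_config_dir", str(Path(path).parent))
    return cfg


def _resolve(cfg: dict, p: str) -> Path:
    base = Path(cfg.get("_config_dir", "."))
    q = Path(p)
    return q if q.is_absolute() else base / q


def validate_config(cfg: dict) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    errs: list[str] = []
    for k in _REQUIRED_KEYS:
        if k not in cfg:
            errs.append(f"missing required key: {k}")
    unknown = sorted(set(cfg) - set(_KNOWN_KEYS) - {"_config_dir"})
    if unknown:
        errs.append(f"unknown config keys: {unknown}")
    tracks = cfg.get("tracks")
    if isinstance(tracks, dict):
        for kind in ("dhs", "ctcf", "states"):
            if kind not in tracks:
                errs.append(f"tracks.{kind} missing")
            elif not _resolve(cfg, tracks[kind]).exists():
                errs.append(f"tracks.{kind}: file not found: {tracks[kind]}")
    elif "tracks" in cfg:
        errs.append("tracks must be a mapping {dhs, ctcf, states}")
    if "build" in cfg and not _resolve(cfg, cfg["build"]).exists():
        errs.append(f"build: file not found: {cfg['build']}")
    if "state_rules" in cfg and not isinstance(cfg.get("state_rules"), dict):
        errs.append("state_rules must be a mapping")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        errs.append("seed must be an integer")
    if cfg.get("score_normalization", "max") not in ("max", "unit"):
        errs.append("score_normalization must be 'max' or 'unit'")
    try:
        SimulationParams(**(cfg.get("params") or {})).require_valid()
    except (TypeError, ValueError) as exc:
        errs.append(f"params: {exc}")
    return errs


def _parse_interval(s) -> tuple[int, int]:
    if isinstance(s, (list, tuple)):
        return int(s[0]), int(s[1])
    a, b = str(s).replace(":", "-").split("-")[-2:]
    return int(a), int(b)


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: dict, progress: bool = False) -> Path:
    """Run every stage and return the output directory.

    Layout: ``annotations/`` (lifted tracks + bead table), ``trajectories/``
    (snapshot text + metadata), ``maps/`` (contact matrix + TAD calls),
    ``profiles/`` (virtual 4C bedGraphs), ``metrics/`` (geometry and
    expression proxies), and ``manifest.json``.
    """
    errs = validate_config(cfg)
    if errs:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errs))
    outdir = _resolve(cfg, cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}, "name": cfg.get("name", "run")}

    # ---- build & annotate -------------------------------------------------
    build = read_build_spec(_resolve(cfg, cfg["build"]))
    tracks = {kind: read_bed(_resolve(cfg, cfg["tracks"][kind]), kind)
              for kind in ("dhs", "ctcf", "states")}
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    lifted = {}
    lift_reports = {}
    for kind, ivs in tracks.items():
        lifted[kind], rep = lift_track(ivs, build)
        lift_reports[kind] = rep.as_dict()
        write_bed(lifted[kind], ann_dir / f"{kind}.lifted.bed")
    annotation = annotate_beads(
        build, lifted["dhs"], lifted["ctcf"], lifted["states"],
        state_rules=cfg["state_rules"],
        score_normalization=cfg.get("score_normalization", "max"),
    )
    annotation.to_tsv(ann_dir / "beads.tsv")
    manifest["stages"]["annotate"] = {
        "liftover": lift_reports,
        "annotation_checksum": annotation.checksum(),
        "n_beads": annotation.n_beads,
    }

    # ---- simulate ---------------------------------------------------------
    params = SimulationParams(**(cfg.get("params") or {}))
    params = params.replace(seed=derive_seed(seed, "simulate"))
    ensemble = run_simulation(annotation, params, progress=progress)
    traj_dir = outdir / "trajectories"
    ensemble.save(traj_dir)
    manifest["stages"]["simulate"] = {
        "seed": params.seed,
        "params": params.as_dict(),
        "n_samples": ensemble.n_samples,
        "trajectory_checksum": _sha256_file(traj_dir / "trajectory.tsv"),
        "block_rejections": ensemble.metadata.get("block_rejections", {}),
    }

    # ---- observables ------------------------------------------------------
    obs = cfg.get("observables") or {}
    bin_size = int(obs.get("bin_size", 10_000))
    cutoff = params.contact_cutoff
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    cmap = contact_map(ensemble, bin_size=bin_size, cutoff=cutoff)
    cmap.to_tsv(maps_dir / "contacts.tsv")
    call = insulation_and_boundaries(cmap)
    call.to_bed(maps_dir / "boundaries.bed", chrom=build.name)
    np.savetxt(maps_dir / "insulation.tsv", call.insulation, fmt="%.6g")
    np.savetxt(maps_dir / "directionality.tsv", call.directionality, fmt="%.6g")
    manifest["stages"]["maps"] = {
        "bin_size": bin_size,
        "n_boundaries": int(len(call.boundaries)),
        "boundaries_bp": [int(b) for b in call.boundaries],
    }

    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for i, vp in enumerate(obs.get("viewpoints", [])):
        profile = virtual_4c(ensemble, _parse_interval(vp), cutoff=cutoff)
        profile.to_bedgraph(prof_dir / f"viewpoint_{i}.bedgraph", chrom=build.name)

    metrics: dict = {}
    for i, probe in enumerate(obs.get("probes", [])):
        iv = _parse_interval(probe)
        rg = geometry_over_ensemble(ensemble, iv, "rg")
        vol = geometry_over_ensemble(ensemble, iv, "volume")
        metrics[f"probe_{i}"] = {
            "interval": list(iv),
            "mean_rg_sigma": rg.mean(),
            "mean_volume_sigma3": vol.mean(),
        }
    enh_labels = obs.get("enhancer_states", [])
    enh_beads = annotation.beads_with_state(enh_labels) if enh_labels else np.array([], int)
    for i, prom in enumerate(obs.get("promoters", [])):
        iv = promoter_interval(int(prom["tss"]), prom.get("strand", "+"))
        entry = {"promoter": list(iv),
                 "bound_fraction": bound_fraction(ensemble, iv, cutoff)}
        if len(enh_beads):
            entry["enhancer_contact_fraction"] = enhancer_contact_fraction(
                ensemble, iv, enh_beads, cutoff)
        metrics[f"promoter_{i}"] = entry
    metrics_dir = outdir / "metrics"
    metrics_dir.mkdir(exist_ok=True)
    (metrics_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest["stages"]["metrics"] = metrics

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
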