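"""Simulation parameters and flat key-value config handling.

All quantities are in reduced Langevin-dynamics units: lengths in sigma
(one sigma maps to roughly 21.8 nm of chromatin), energies in kT
(temperature is fixed at 1), time in tau = sigma * sqrt(m / kT) with bead
mass m = 1. Defaults are desk-scale and provisional; every field can be
overridden from a flat config file (one ``key: value`` per line, YAML
mapping syntax). Unknown keys are an error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SimulationParams", "read_params", "write_params"]


@dataclass
class SimulationParams:
    # system composition
    n_copies: int = 1  # polymer copies sharing one confinement volume
    box_density: float = 0.015  # chromatin volume fraction in the confinement sphere
    # integrator
    dt: float = 0.01  # time step (tau)
    gamma: float = 1.0  # friction (1/tau)
    temperature: float = 1.0  # kT, fixed reduced units
    # bridging proteins, per copy
    n_active: int = 10
    n_het: int = 4
    n_pcg: int = 4
    eps_active: float = 4.0  # binding energies (kT)
    eps_het: float = 4.0
    eps_pcg: float = 4.0
    protein_switch_rate: float = 2e-4  # per-step on<->off probability
    protein_diameter: float = 1.0  # sigma
    # loop extrusion, per copy
    n_extruders: int = 8
    extrude_interval: int = 50  # dynamics steps between extrusion updates
    unload_prob: float = 0.01  # per-update unbinding probability (loop turnover)
    capture_radius: float = 4.0  # sigma; 3D gate for leg steps
    extruder_k: float = 10.0  # leg-pair spring constant (kT / sigma^2)
    # heteromorphic fiber
    open_diameter: float = 0.8  # sigma
    compact_diameter: float = 1.1  # sigma
    open_persistence: float = 3.0  # bending modulus along open runs (kT)
    eps_compact: float = 0.5  # compact-compact attraction (kT), crumples locally
    compact_attr_range: int = 20  # beads; crumpling attraction is local in genomic distance
    crumple_k: float = 10.0  # second-neighbour spring on compact runs (kT / sigma^2)
    # observables / protocol
    contact_cutoff: float = 3.5  # sigma
    equilibration_steps: int = 5000
    snapshot_interval: int = 250
    n_snapshots: int = 200
    seed: int = 0

    def validate(self) -> list[str]:
        """Return a list of problems (empty when valid)."""
        errs: list[str] = []

        def chk(cond, msg):
            if not cond:
                errs.append(msg)

        for f in ("n_copies", "n_active", "n_het", "n_pcg", "n_extruders",
                  "extrude_interval", "equilibration_steps", "snapshot_interval",
                  "n_snapshots", "compact_attr_range"):
            v = getattr(self, f)
            chk(isinstance(v, int) and v >= 0, f"{f} must be a non-negative integer, got {v!r}")
        chk(self.n_copies >= 1, "n_copies must be >= 1")
        chk(self.extrude_interval >= 1, "extrude_interval must be >= 1")
        chk(self.snapshot_interval >= 1, "snapshot_interval must be >= 1")
        chk(self.dt > 0, "dt must be > 0")
        chk(self.gamma > 0, "gamma must be > 0")
        chk(self.temperature > 0, "temperature must be > 0")
        chk(0 < self.box_density < 0.5, "box_density must lie in (0, 0.5)")
        for f in ("unload_prob", "protein_switch_rate"):
            v = getattr(self, f)
            chk(0 <= v <= 1, f"{f} must lie in [0, 1], got {v!r}")
        for f in ("open_diameter", "compact_diameter", "protein_diameter",
                  "contact_cutoff", "capture_radius", "extruder_k"):
            chk(getattr(self, f) > 0, f"{f} must be > 0")
        for f in ("eps_active", "eps_het", "eps_pcg", "eps_compact", "open_persistence",
                  "crumple_k"):
            chk(getattr(self, f) >= 0, f"{f} must be >= 0")
        chk(isinstance(self.seed, int), "seed must be an integer")
        return errs

    def require_valid(self) -> "SimulationParams":
        errs = self.validate()
        if errs:
            raise ValueError("invalid simulation parameters:\n  " + "\n  ".join(errs))
        return self

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_params(path) -> SimulationParams:
    """Read a flat key-value config; keys mirror SimulationParams fields
    exactly and unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(SimulationParams)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {unknown}")
    return SimulationParams(**data).require_valid()


def write_params(params: SimulationParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)
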