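"""Polymer dynamics driver: bridging proteins, heteromorphic fiber, loop extrusion.

The simulated system is ``n_copies`` identical bead chains (one per copy of
the locus) plus diffusing bridging proteins, confined in a sphere whose
radius matches the requested chromatin volume fraction. Chains evolve by
Langevin dynamics (see :mod:`chromoloop._kernels`); every
``extrude_interval`` dynamics steps the loop extruders take one stochastic
1D step along each chain, gated by oriented CTCF anchors, and proteins may
toggle their binding state.

CTCF gating convention: a "+"-oriented anchor halts right-to-left travel —
a left-moving extruder leg sitting on a "+" (or "both") anchor bead is
blocked, with probability ``ctcf_occupancy``, from stepping further left;
symmetrically a "-" anchor blocks right-moving legs. A convergent
"+ ... -" pair therefore traps extruders with their legs exactly on the
anchor beads, stabilising the loop — the classic convergent-CTCF TAD
mechanism.

Copies interact only through excluded volume (and shared diffusing
proteins); statistically each copy snapshot is an independent sample, a
"cell" of the simulated population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import _kernels
from .annotate import BeadAnnotation, CTCF_BOTH, CTCF_MINUS, CTCF_PLUS
from .params import SimulationParams

__all__ = [
    "SystemState",
    "Conformation",
    "Ensemble",
    "init_system",
    "step_dynamics",
    "update_extruders",
    "run_simulation",
]

K_BOND = 100.0  # backbone spring (kT / sigma^2)
K_WALL = 20.0  # confinement wall (kT / sigma^2)
WARMUP_STEPS = 2000  # overdamped, displacement-capped overlap annealing
MAX_WARMUP_DISP = 0.1  # sigma per step during warmup


@dataclass
class Conformation:
    """One polymer copy's bead positions (sigma units) in one snapshot."""

    positions: np.ndarray  # (n_beads, 3)
    box: float  # confinement sphere radius (sigma)

    def __post_init__(self):
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")


@dataclass
class SystemState:
    """Mutable simulation state: all particles plus extruder bookkeeping.

    Particle layout: beads of copy 0, copy 1, ... then all proteins.
    """

    pos: np.ndarray  # (M, 3)
    vel: np.ndarray  # (M, 3)
    rad: np.ndarray  # (M,)
    flags: np.ndarray  # (n_bead_total,) uint8 bitmask: 1 active, 2 het, 4 pcg, 8 open
    copy_of: np.ndarray  # (n_bead_total,) int32
    open_bead: np.ndarray  # (n_beads,) bool (same for every copy)
    prot_species: np.ndarray  # (n_prot,) int8: 0 active, 1 het, 2 pcg
    prot_on: np.ndarray  # (n_prot,) uint8
    ext_a: np.ndarray  # (n_slots,) int64 local bead index, -1 unloaded
    ext_b: np.ndarray
    ext_copy: np.ndarray  # (n_slots,) int64
    n_beads: int
    n_copies: int
    R_conf: float
    step_count: int = 0
    block_rejections: dict = field(default_factory=dict)  # bead -> CTCF rejections

    @property
    def n_bead_total(self) -> int:
        return self.n_beads * self.n_copies

    @property
    def n_proteins(self) -> int:
        return len(self.prot_species)

    def bead_positions(self, copy: int) -> np.ndarray:
        base = copy * self.n_beads
        return self.pos[base : base + self.n_beads]


@dataclass
class Ensemble:
    """The population of simulated cells: snapshots x copies of conformations."""

    bead_pos: np.ndarray  # (S, n_copies, n_beads, 3)
    protein_pos: np.ndarray  # (S, n_prot, 3)
    protein_species: np.ndarray  # (n_prot,)
    protein_on: np.ndarray  # (S, n_prot) bool
    extruders: np.ndarray  # (S, n_slots, 3): copy, left, right (-1 unloaded)
    annotation: BeadAnnotation
    box: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_snapshots(self) -> int:
        return self.bead_pos.shape[0]

    @property
    def n_copies(self) -> int:
        return self.bead_pos.shape[1]

    @property
    def n_beads(self) -> int:
        return self.bead_pos.shape[2]

    @property
    def n_samples(self) -> int:
        """Independent conformations = snapshots x copies."""
        return self.n_snapshots * self.n_copies

    def iter_conformations(self) -> Iterator[np.ndarray]:
        """Yield every (snapshot, copy) bead-position array."""
        for s in range(self.n_snapshots):
            for c in range(self.n_copies):
                yield self.bead_pos[s, c]

    def conformation(self, snapshot: int, copy: int = 0) -> Conformation:
        return Conformation(self.bead_pos[snapshot, copy], self.box)

    # -- I/O ---------------------------------------------------------------
    def save(self, outdir) -> None:
        """Write the trajectory as documented column text plus metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "trajectory.tsv", "w") as fh:
            fh.write("snapshot\tcopy\tbead\tx\ty\tz\n")
            for s in range(self.n_snapshots):
                for c in range(self.n_copies):
                    P = self.bead_pos[s, c]
                    for b in range(self.n_beads):
                        fh.write(f"{s}\t{c}\t{b}\t{P[b,0]:.6f}\t{P[b,1]:.6f}\t{P[b,2]:.6f}\n")
        with open(outdir / "proteins.tsv", "w") as fh:
            fh.write("snapshot\tprotein\tspecies\tbinding_on\tx\ty\tz\n")
            for s in range(self.n_snapshots):
                for p in range(len(self.protein_species)):
                    q = self.protein_pos[s, p]
                    fh.write(
                        f"{s}\t{p}\t{int(self.protein_species[p])}\t"
                        f"{int(self.protein_on[s, p])}\t{q[0]:.6f}\t{q[1]:.6f}\t{q[2]:.6f}\n"
                    )
        with open(outdir / "extruders.tsv", "w") as fh:
            fh.write("snapshot\tslot\tcopy\tleft\tright\n")
            for s in range(self.n_snapshots):
                for k in range(self.extruders.shape[1]):
                    c, a, b = self.extruders[s, k]
                    fh.write(f"{s}\t{k}\t{c}\t{a}\t{b}\n")
        meta = dict(self.metadata)
        meta.update(box=self.box, n_snapshots=self.n_snapshots,
                    n_copies=self.n_copies, n_beads=self.n_beads)
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        self.annotation.to_tsv(outdir / "annotation.tsv")

    @classmethod
    def load(cls, outdir) -> "Ensemble":
        import pandas as pd

        outdir = Path(outdir)
        meta = json.loads((outdir / "metadata.json").read_text())
        S, C, N = meta["n_snapshots"], meta["n_copies"], meta["n_beads"]
        tr = pd.read_csv(outdir / "trajectory.tsv", sep="\t")
        bead_pos = np.zeros((S, C, N, 3))
        bead_pos[tr["snapshot"], tr["copy"], tr["bead"], 0] = tr["x"]
        bead_pos[tr["snapshot"], tr["copy"], tr["bead"], 1] = tr["y"]
        bead_pos[tr["snapshot"], tr["copy"], tr["bead"], 2] = tr["z"]
        pr = pd.read_csv(outdir / "proteins.tsv", sep="\t")
        n_prot = int(pr["protein"].max()) + 1 if len(pr) else 0
        protein_pos = np.zeros((S, n_prot, 3))
        protein_on = np.zeros((S, n_prot), dtype=bool)
        species = np.zeros(n_prot, dtype=np.int8)
        if len(pr):
            protein_pos[pr["snapshot"], pr["protein"], 0] = pr["x"]
            protein_pos[pr["snapshot"], pr["protein"], 1] = pr["y"]
            protein_pos[pr["snapshot"], pr["protein"], 2] = pr["z"]
            protein_on[pr["snapshot"], pr["protein"]] = pr["binding_on"].astype(bool)
            species[pr.loc[pr["snapshot"] == 0, "protein"]] = pr.loc[
                pr["snapshot"] == 0, "species"
            ]
        ex = pd.read_csv(outdir / "extruders.tsv", sep="\t")
        n_slots = int(ex["slot"].max()) + 1 if len(ex) else 0
        extruders = np.full((S, n_slots, 3), -1, dtype=np.int64)
        if len(ex):
            extruders[ex["snapshot"], ex["slot"], 0] = ex["copy"]
            extruders[ex["snapshot"], ex["slot"], 1] = ex["left"]
            extruders[ex["snapshot"], ex["slot"], 2] = ex["right"]
        annotation = BeadAnnotation.from_tsv(outdir / "annotation.tsv")
        return cls(bead_pos, protein_pos, species, protein_on, extruders,
                   annotation, float(meta["box"]), metadata=meta)


def _confinement_radius(n_particles: int, density: float) -> float:
    """Sphere radius giving volume fraction ``density`` for ``n_particles``
    reference particles of diameter 1 sigma. The reference diameter (not
    each particle's actual one) is used so that the confinement volume
    tracks genomic content, not fiber state: an all-open and an all-compact
    locus of equal length get the same nuclear volume."""
    return float((n_particles * 0.5**3 / density) ** (1.0 / 3.0))


def init_system(annotation: BeadAnnotation, params: SimulationParams,
                rng: np.random.Generator | None = None) -> SystemState:
    """Place chains as confined random walks plus uniformly scattered proteins.

    Overlaps are permitted at t=0; :func:`run_simulation` anneals them away
    with a displacement-capped overdamped warm-up before production steps.
    """
    params.require_valid()
    n = annotation.n_beads
    if n == 0:
        raise ValueError("empty annotation")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    C = params.n_copies
    n_prot_per = params.n_active + params.n_het + params.n_pcg
    NP = C * n_prot_per
    NB = C * n
    M = NB + NP

    bead_rad = np.where(annotation.open_fiber, params.open_diameter, params.compact_diameter) / 2.0
    rad = np.empty(M)
    rad[:NB] = np.tile(bead_rad, C)
    rad[NB:] = params.protein_diameter / 2.0
    R = _confinement_radius(M, params.box_density)
    bond_max = np.max(bead_rad) * 2
    if R < 3 * bond_max:
        raise ValueError(
            f"box_density {params.box_density} leaves no room to place chains "
            f"(confinement radius {R:.2f} sigma)"
        )

    flags = np.zeros(n, dtype=np.uint8)
    flags |= annotation.active_site.astype(np.uint8) * 1
    flags |= annotation.het_site.astype(np.uint8) * 2
    flags |= annotation.pcg_site.astype(np.uint8) * 4
    flags |= annotation.open_fiber.astype(np.uint8) * 8
    flags = np.tile(flags, C)
    copy_of = np.repeat(np.arange(C, dtype=np.int32), n)

    pos = np.zeros((M, 3))
    for c in range(C):
        base = c * n
        # start point well inside the sphere
        start = rng.normal(size=3)
        start *= (0.5 * R * rng.random() ** (1 / 3)) / max(np.linalg.norm(start), 1e-9)
        pos[base] = start
        for i in range(1, n):
            step = rng.normal(size=3)
            step *= (bead_rad[i - 1] + bead_rad[i]) / max(np.linalg.norm(step), 1e-9)
            cand = pos[base + i - 1] + step
            # reflect back toward the centre if the walk hits the wall
            rr = np.linalg.norm(cand)
            if rr > R - 1.0:
                cand *= (R - 1.0) / rr
            pos[base + i] = cand
    if NP:
        u = rng.normal(size=(NP, 3))
        u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-9)
        pos[NB:] = u * (R * rng.random(size=(NP, 1)) ** (1 / 3))

    species = np.concatenate([
        np.full(params.n_active, 0, dtype=np.int8),
        np.full(params.n_het, 1, dtype=np.int8),
        np.full(params.n_pcg, 2, dtype=np.int8),
    ])
    prot_species = np.tile(species, C)
    prot_on = np.ones(NP, dtype=np.uint8)

    n_slots = C * params.n_extruders
    state = SystemState(
        pos=pos,
        vel=np.zeros((M, 3)),
        rad=rad,
        flags=flags,
        copy_of=copy_of,
        open_bead=annotation.open_fiber.astype(np.bool_),
        prot_species=prot_species,
        prot_on=prot_on,
        ext_a=np.full(n_slots, -1, dtype=np.int64),
        ext_b=np.full(n_slots, -1, dtype=np.int64),
        ext_copy=np.repeat(np.arange(C, dtype=np.int64), params.n_extruders),
        n_beads=n,
        n_copies=C,
        R_conf=R,
    )
    return state


def step_dynamics(state: SystemState, n_steps: int, params: SimulationParams,
                  overdamped: bool = False, max_disp: float = MAX_WARMUP_DISP) -> SystemState:
    """Advance ``n_steps`` Langevin steps in place; aborts on non-finite output."""
    _kernels.integrate(
        state.pos, state.vel, state.rad, state.flags, state.copy_of,
        state.n_bead_total, state.n_beads, state.n_copies,
        state.open_bead, state.prot_species, state.prot_on,
        state.ext_a, state.ext_b, state.ext_copy,
        n_steps, params.dt, params.gamma, params.temperature,
        K_BOND, params.open_persistence, params.crumple_k,
        params.eps_active, params.eps_het, params.eps_pcg, params.eps_compact,
        params.compact_attr_range, params.extruder_k, state.R_conf, K_WALL,
        overdamped, max_disp,
    )
    state.step_count += n_steps
    if not np.all(np.isfinite(state.pos)):
        bad = np.argwhere(~np.isfinite(state.pos))[0]
        raise FloatingPointError(
            f"non-finite coordinate for particle {bad[0]} after step {state.step_count}"
        )
    return state


def update_extruders(state: SystemState, annotation: BeadAnnotation,
                     params: SimulationParams, rng: np.random.Generator) -> SystemState:
    """One stochastic extrusion update: unload / load / step each leg once.

    Left legs step i -> i-1 and are blocked (with probability
    ``ctcf_occupancy``) while sitting on a "+" or "both" anchor; right legs
    step j -> j+1 and are blocked on "-" or "both" anchors. Steps onto
    occupied beads, off the chain, or beyond the 3D capture radius are
    rejected.
    """
    n = state.n_beads
    ctcf = annotation.ctcf
    occ = annotation.ctcf_occupancy
    cap2 = params.capture_radius**2

    occupied: list[set[int]] = [set() for _ in range(state.n_copies)]
    for k in range(len(state.ext_a)):
        if state.ext_a[k] >= 0:
            c = int(state.ext_copy[k])
            occupied[c].add(int(state.ext_a[k]))
            occupied[c].add(int(state.ext_b[k]))

    # unload
    for k in range(len(state.ext_a)):
        if state.ext_a[k] >= 0 and rng.random() < params.unload_prob:
            c = int(state.ext_copy[k])
            occupied[c].discard(int(state.ext_a[k]))
            occupied[c].discard(int(state.ext_b[k]))
            state.ext_a[k] = -1
            state.ext_b[k] = -1

    # load vacant slots at random unoccupied adjacent pairs
    for k in range(len(state.ext_a)):
        if state.ext_a[k] >= 0:
            continue
        c = int(state.ext_copy[k])
        for _ in range(20):
            i = int(rng.integers(0, n - 1))
            if i not in occupied[c] and (i + 1) not in occupied[c]:
                state.ext_a[k] = i
                state.ext_b[k] = i + 1
                occupied[c].update((i, i + 1))
                break

    # step legs outward
    for k in range(len(state.ext_a)):
        a = int(state.ext_a[k])
        if a < 0:
            continue
        b = int(state.ext_b[k])
        c = int(state.ext_copy[k])
        base = c * n
        # left leg a -> a-1
        if a - 1 >= 0 and (a - 1) not in occupied[c]:
            if ctcf[a] in (CTCF_PLUS, CTCF_BOTH) and rng.random() < occ[a]:
                state.block_rejections[a] = state.block_rejections.get(a, 0) + 1
            else:
                d2 = np.sum((state.pos[base + a - 1] - state.pos[base + b]) ** 2)
                if d2 <= cap2:
                    occupied[c].discard(a)
                    a -= 1
                    occupied[c].add(a)
                    state.ext_a[k] = a
        # right leg b -> b+1
        if b + 1 < n and (b + 1) not in occupied[c]:
            if ctcf[b] in (CTCF_MINUS, CTCF_BOTH) and rng.random() < occ[b]:
                state.block_rejections[b] = state.block_rejections.get(b, 0) + 1
            else:
                d2 = np.sum((state.pos[base + a] - state.pos[base + b + 1]) ** 2)
                if d2 <= cap2:
                    occupied[c].discard(b)
                    b += 1
                    occupied[c].add(b)
                    state.ext_b[k] = b

    # protein binding-state switching at the same cadence
    if params.protein_switch_rate > 0 and state.n_proteins:
        p_update = 1.0 - (1.0 - params.protein_switch_rate) ** params.extrude_interval
        flip = rng.random(state.n_proteins) < p_update
        state.prot_on[flip] ^= 1
    return state


def run_simulation(annotation: BeadAnnotation, params: SimulationParams,
                   progress: bool = False) -> Ensemble:
    """Full protocol: init, warm-up, equilibrate, then record snapshots.

    Snapshots are taken every ``snapshot_interval`` steps (rounded to a
    whole number of extrusion intervals); ``n_snapshots`` are recorded per
    copy, so the ensemble holds ``n_copies * n_snapshots`` conformations.
    Identical params (including seed) give bit-identical ensembles.
    """
    params.require_valid()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC0FFEE]))
    _kernels.seed_rng(params.seed % (2**31))
    state = init_system(annotation, params, rng=rng)

    E = params.extrude_interval
    snap_every = max(1, round(params.snapshot_interval / E)) * E

    # overlap annealing: overdamped, displacement-capped
    step_dynamics(state, WARMUP_STEPS, params, overdamped=True)

    def advance(n_steps):
        done = 0
        while done < n_steps:
            block = min(E, n_steps - done)
            step_dynamics(state, block, params)
            done += block
            update_extruders(state, annotation, params, rng)

    advance(params.equilibration_steps)

    S = params.n_snapshots
    NB, NP = state.n_bead_total, state.n_proteins
    bead_pos = np.empty((S, params.n_copies, annotation.n_beads, 3))
    protein_pos = np.empty((S, NP, 3))
    protein_on = np.empty((S, NP), dtype=bool)
    extruders = np.empty((S, len(state.ext_a), 3), dtype=np.int64)
    for s in range(S):
        advance(snap_every)
        bead_pos[s] = state.pos[:NB].reshape(params.n_copies, annotation.n_beads, 3)
        protein_pos[s] = state.pos[NB:]
        protein_on[s] = state.prot_on.astype(bool)
        extruders[s, :, 0] = state.ext_copy
        extruders[s, :, 1] = state.ext_a
        extruders[s, :, 2] = state.ext_b
        if progress and (s + 1) % 50 == 0:
            print(f"  snapshot {s + 1}/{S}")

    meta = {
        "seed": params.seed,
        "params": params.as_dict(),
        "annotation_checksum": annotation.checksum(),
        "bead_size": annotation.bead_size,
        "locus_name": annotation.locus_name,
        "block_rejections": {str(k): v for k, v in sorted(state.block_rejections.items())},
    }
    return Ensemble(bead_pos, protein_pos, state.prot_species.copy(), protein_on,
                    extruders, annotation, state.R_conf, metadata=meta)
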