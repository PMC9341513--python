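"""Synthetic loci with known ground truth.

These generators emulate the *structure* of real DNase/CTCF/chromatin-state
input tracks — TAD-scale convergent CTCF anchor pairs, DHS clusters at
promoters and enhancers, contiguous state blocks — at a few hundred kbp so
that every pipeline stage can be exercised and validated without any
external data. Ground truth (planted anchors, binder beads, boundaries) is
returned machine-readable alongside each fixture.

Default state labels and their model categories::

    Open  -> active_open   (H3K27ac-like, open fiber)
    Enh   -> active_open   (enhancer-associated, open fiber)
    Het   -> het           (H3K9me3-like)
    Pcg   -> pcg           (H3K27me3-like)
    Quies -> neutral

CTCF fixture scores are written directly as occupancies in [0, 1]; use
``score_normalization="unit"`` when annotating fixture tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import BEAD_SIZE
from .build import LocusBuild, SourceSegment, compose_build
from .intervals import GenomicInterval

__all__ = [
    "ToyLocusSpec",
    "DEFAULT_STATE_RULES",
    "make_toy_locus",
    "make_reference_conformation",
    "make_rearrangement_cases",
    "make_breakpoint_scan",
]

DEFAULT_STATE_RULES = {
    "Open": "active_open",
    "Enh": "active_open",
    "Het": "het",
    "Pcg": "pcg",
    "Quies": "neutral",
}


@dataclass
class ToyLocusSpec:
    """Recipe for a planted-TAD toy locus.

    TADs tile the locus; each TAD gets a convergent anchor pair ("+" on its
    left edge bead, "-" on its right edge bead) with the given occupancy.
    ``dhs_clusters`` is a list of (bead position, n_sites); ``state_blocks``
    a list of ((start_bead, end_bead), state_label) with half-open bead
    ranges that must not overlap.
    """

    n_tads: int = 3
    tad_length: int = 100  # beads
    dhs_clusters: list = field(default_factory=list)
    state_blocks: list = field(default_factory=list)
    anchor_occupancy: float = 1.0
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.n_tads * self.tad_length


def make_toy_locus(spec: ToyLocusSpec, chrom: str = "chrT") -> tuple[LocusBuild, dict, dict]:
    """Build BED-style tracks for a planted-TAD locus.

    Returns (identity build, tracks, ground_truth) where tracks has keys
    ``dhs``, ``ctcf``, ``states`` and ground_truth records planted anchor
    beads, boundary beads, and binder beads.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_beads * BEAD_SIZE
    build = compose_build([SourceSegment(chrom, 0, L, "+")], name=f"toy{spec.n_tads}tad")

    ctcf = []
    anchor_beads = []
    for t in range(spec.n_tads):
        left = t * spec.tad_length
        right = (t + 1) * spec.tad_length - 1
        for bead, orient in ((left, "+"), (right, "-")):
            mid = bead * BEAD_SIZE + BEAD_SIZE // 2
            ctcf.append(
                GenomicInterval(chrom, mid - 100, mid + 100, label=f"anchor_t{t}{orient}",
                                orientation=orient, score=spec.anchor_occupancy)
            )
            anchor_beads.append((bead, orient))

    dhs = []
    dhs_beads = []
    for pos, n_sites in spec.dhs_clusters:
        for k in range(n_sites):
            bead = pos + k
            if bead >= spec.n_beads:
                raise ValueError(f"DHS cluster at bead {pos} runs off the locus")
            off = int(rng.integers(100, BEAD_SIZE - 300))
            start = bead * BEAD_SIZE + off
            dhs.append(GenomicInterval(chrom, start, start + 200, label=f"dhs_{bead}"))
            dhs_beads.append(bead)

    states = []
    covered = np.zeros(spec.n_beads, dtype=bool)
    for (b0, b1), label in spec.state_blocks:
        if label not in DEFAULT_STATE_RULES:
            raise ValueError(f"unknown state label {label!r}")
        if not (0 <= b0 < b1 <= spec.n_beads):
            raise ValueError(f"state block ({b0}, {b1}) outside locus")
        if covered[b0:b1].any():
            raise ValueError(f"state block ({b0}, {b1}) overlaps an earlier block")
        covered[b0:b1] = True
        states.append(
            GenomicInterval(chrom, b0 * BEAD_SIZE, b1 * BEAD_SIZE, label=label)
        )

    tracks = {"dhs": dhs, "ctcf": sorted(ctcf, key=lambda iv: iv.start),
              "states": states}
    truth = {
        "n_beads": spec.n_beads,
        "tad_length": spec.tad_length,
        "anchor_beads": anchor_beads,
        "boundary_beads": [t * spec.tad_length for t in range(1, spec.n_tads)],
        "dhs_beads": sorted(set(dhs_beads)),
        "state_blocks": [((b0, b1), lab) for (b0, b1), lab in spec.state_blocks],
        "anchor_occupancy": spec.anchor_occupancy,
    }
    return build, tracks, truth


def make_reference_conformation(kind: str, n: int, seed: int = 0) -> np.ndarray:
    """Deterministic coordinates for closed-form observable tests.

    kinds: ``line`` (unit spacing on x), ``ring`` (unit-spaced circle),
    ``tetrahedron`` (4 beads, unit edges), ``random-walk`` (unit steps).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "line":
        P = np.zeros((n, 3))
        P[:, 0] = np.arange(n)
        return P
    if kind == "ring":
        R = 0.5 / np.sin(np.pi / max(n, 2)) if n > 1 else 0.0
        th = 2 * np.pi * np.arange(n) / max(n, 1)
        return np.column_stack([R * np.cos(th), R * np.sin(th), np.zeros(n)])
    if kind == "tetrahedron":
        if n != 4:
            raise ValueError("tetrahedron needs n=4")
        P = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        return P / np.sqrt(8)  # unit edge length
    if kind == "random-walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n - 1, 3)) if n > 1 else np.zeros((0, 3))
        if n > 1:
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) if n > 1 else np.zeros((1, 3))
    raise ValueError(f"unknown conformation kind {kind!r}")


# ---------------------------------------------------------------------------
# rearrangement cases


def _enhancer_donor(chrom: str, n_beads: int, rng: np.random.Generator):
    """A donor segment carrying a DHS-cluster super-enhancer."""
    dhs, states = [], []
    states.append(GenomicInterval(chrom, 0, n_beads * BEAD_SIZE, label="Enh"))
    for bead in range(1, n_beads - 1):
        off = int(rng.integers(100, BEAD_SIZE - 300))
        start = bead * BEAD_SIZE + off
        dhs.append(GenomicInterval(chrom, start, start + 200, label=f"enh_dhs_{bead}"))
    return dhs, states


def _base_locus(chrom: str, n_beads: int, tss_bead: int, enh_far: tuple[int, int],
                rng: np.random.Generator):
    """Base locus: one gene (promoter DHS at the TSS bead), a far weak
    enhancer block, anchors at the locus edges, neutral elsewhere."""
    dhs = []
    # promoter DHS (1 kbp upstream of TSS on '+' strand = bead tss_bead - 1)
    p = (tss_bead - 1) * BEAD_SIZE + 400
    dhs.append(GenomicInterval(chrom, p, p + 200, label="promoter_dhs"))
    e0, e1 = enh_far
    states = [GenomicInterval(chrom, e0 * BEAD_SIZE, e1 * BEAD_SIZE, label="Enh")]
    for bead in range(e0, e1):
        off = int(rng.integers(100, BEAD_SIZE - 300))
        start = bead * BEAD_SIZE + off
        dhs.append(GenomicInterval(chrom, start, start + 200, label=f"far_dhs_{bead}"))
    ctcf = [
        GenomicInterval(chrom, 400, 600, label="anchor_L", orientation="+", score=1.0),
        GenomicInterval(chrom, (n_beads - 1) * BEAD_SIZE + 400,
                        (n_beads - 1) * BEAD_SIZE + 600, label="anchor_R",
                        orientation="-", score=1.0),
    ]
    return dhs, ctcf, states


def make_rearrangement_cases(seed: int = 0) -> dict:
    """Four canonical rearrangement fixtures.

    * ``identity`` — the unrearranged base locus (gene plus a far enhancer).
    * ``insertion`` — an enhancer-donor segment inserted just downstream of
      the promoter (the enhancer-hijack scenario).
    * ``translocation`` — reciprocal join of the base locus's left arm to
      the reversed donor chromosome ("-" strand segment).
    * ``epigenome_swap`` — the identity build carrying the *insertion*
      condition's chromatin states on the unrearranged genome (in-silico
      epigenome edit: rearrangement removed, states retained).

    Each case maps to {"build", "tracks", "truth"}. Reference tracks are in
    reference coordinates and must be lifted through the build.
    """
    rng = np.random.default_rng(seed)
    nA = 150  # beads in base locus chrA
    nB = 10  # beads in enhancer donor chrB
    tss_bead = 30
    enh_far = (130, 136)
    insert_at = 35  # beads; insertion point downstream of the gene

    dhsA, ctcfA, statesA = _base_locus("chrA", nA, tss_bead, enh_far, rng)
    dhsB, statesB = _enhancer_donor("chrB", nB, rng)

    LA, LB = nA * BEAD_SIZE, nB * BEAD_SIZE
    tracks = {
        "dhs": sorted(dhsA + dhsB, key=lambda iv: (iv.chrom, iv.start)),
        "ctcf": ctcfA,
        "states": sorted(statesA + statesB, key=lambda iv: (iv.chrom, iv.start)),
    }
    truth_common = {
        "tss_bead": tss_bead,
        "tss_bp": tss_bead * BEAD_SIZE,
        "strand": "+",
        "far_enhancer_beads": list(range(*enh_far)),
        "insert_at_bp": insert_at * BEAD_SIZE,
        "donor_beads": nB,
    }

    identity = compose_build([SourceSegment("chrA", 0, LA, "+")], name="identity")
    insertion = compose_build(
        [
            SourceSegment("chrA", 0, insert_at * BEAD_SIZE, "+"),
            SourceSegment("chrB", 0, LB, "+"),
            SourceSegment("chrA", insert_at * BEAD_SIZE, LA, "+"),
        ],
        name="insertion",
    )
    translocation = compose_build(
        [
            SourceSegment("chrA", 0, 100 * BEAD_SIZE, "+"),
            SourceSegment("chrB", 0, LB, "-"),
        ],
        name="translocation",
    )

    cases = {
        "identity": {"build": identity, "tracks": tracks,
                     "truth": dict(truth_common, inserted=False)},
        "insertion": {"build": insertion, "tracks": tracks,
                      "truth": dict(truth_common, inserted=True,
                                    inserted_beads=list(range(insert_at, insert_at + nB)))},
        "translocation": {"build": translocation, "tracks": tracks,
                          "truth": dict(truth_common, inserted=True,
                                        inserted_beads=list(range(100, 100 + nB)))},
        # epigenome edit: unrearranged genome, donor-condition states kept on
        # the identity build (the donor states simply do not lift -> the
        # remaining edit is the base condition with enhancer states removed
        # near the gene; modelled here as identity build + tracks where the
        # far enhancer keeps its states)
        "epigenome_swap": {"build": identity, "tracks": tracks,
                           "truth": dict(truth_common, inserted=False)},
    }
    return cases


def make_breakpoint_scan(offsets_beads: tuple[int, ...] = (5, 25, 60),
                         seed: int = 0) -> dict:
    """Insertion builds where the enhancer donor lands at increasing
    genomic separation from the promoter (same donor, moved breakpoint);
    enhancer-promoter contacts are expected to weaken with separation."""
    base = make_rearrangement_cases(seed)
    tracks = base["identity"]["tracks"]
    tss_bead = base["identity"]["truth"]["tss_bead"]
    nA = 150
    out = {}
    for off in offsets_beads:
        at = (tss_bead + off) * BEAD_SIZE
        build = compose_build(
            [
                SourceSegment("chrA", 0, at, "+"),
                SourceSegment("chrB", 0, 10 * BEAD_SIZE, "+"),
                SourceSegment("chrA", at, nA * BEAD_SIZE, "+"),
            ],
            name=f"insert_off{off}",
        )
        out[off] = {"build": build, "tracks": tracks,
                    "truth": {"tss_bead": tss_bead, "offset_beads": off,
                              "inserted_beads": list(range(tss_bead + off, tss_bead + off + 10))}}
    return out
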