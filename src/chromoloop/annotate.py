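"""Per-bead polymer annotation derived from lifted 1D tracks.

Each 1-kbp bead of the simulated locus carries the model inputs:

* ``active_site`` — bead overlaps a DNase-hypersensitive site; binding site
  for the active bridging protein (a generic polymerase/TF complex).
* ``het_site`` / ``pcg_site`` — bead majority-covered by a chromatin state
  mapped to heterochromatin (H3K9me3, HP1-like binder) or polycomb
  (H3K27me3, PRC-like binder).
* ``open_fiber`` — bead majority-covered by an H3K27ac-associated state;
  rendered as the thinner, more flexible fiber.
* ``ctcf`` / ``ctcf_occupancy`` — oriented loop-extruder anchor and the
  probability with which it blocks an extruder leg.
* ``state_label`` — dominant chromatin-state label (for enhancer-state
  lookups in the observables).

State labels are mapped to the four model categories through a user-supplied
``state_rules`` mapping; unknown labels are an error so that silent
misconfiguration cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .build import LocusBuild
from .intervals import GenomicInterval

__all__ = [
    "BeadAnnotation",
    "annotate_beads",
    "STATE_CATEGORIES",
    "CTCF_NONE",
    "CTCF_PLUS",
    "CTCF_MINUS",
    "CTCF_BOTH",
]

BEAD_SIZE = 1000  # bp per bead

STATE_CATEGORIES = ("active_open", "het", "pcg", "neutral")

# ctcf codes
CTCF_NONE, CTCF_PLUS, CTCF_MINUS, CTCF_BOTH = 0, 1, 2, 3
_CTCF_STR = {CTCF_NONE: "none", CTCF_PLUS: "+", CTCF_MINUS: "-", CTCF_BOTH: "both"}
_CTCF_CODE = {v: k for k, v in _CTCF_STR.items()}


@dataclass
class BeadAnnotation:
    """Arrays of per-bead polymer properties (one entry per 1-kbp bead)."""

    active_site: np.ndarray  # bool
    het_site: np.ndarray  # bool
    pcg_site: np.ndarray  # bool
    open_fiber: np.ndarray  # bool
    ctcf: np.ndarray  # int8, CTCF_* codes
    ctcf_occupancy: np.ndarray  # float in [0, 1]
    state_label: list[str]
    bead_size: int = BEAD_SIZE
    locus_name: str = "locus"

    def __post_init__(self):
        n = len(self.active_site)
        for arr in (self.het_site, self.pcg_site, self.open_fiber, self.ctcf, self.ctcf_occupancy):
            if len(arr) != n:
                raise ValueError("annotation arrays must share one length")
        if len(self.state_label) != n:
            raise ValueError("state_label length mismatch")
        if np.any((self.ctcf == CTCF_NONE) & (self.ctcf_occupancy != 0)):
            raise ValueError("ctcf_occupancy must be 0 where ctcf is none")
        if np.any((self.ctcf_occupancy < 0) | (self.ctcf_occupancy > 1)):
            raise ValueError("ctcf_occupancy must lie in [0, 1]")

    @property
    def n_beads(self) -> int:
        return len(self.active_site)

    def ctcf_str(self, i: int) -> str:
        return _CTCF_STR[int(self.ctcf[i])]

    def beads_with_state(self, labels: Iterable[str]) -> np.ndarray:
        """Bead indices whose dominant state label is in ``labels``."""
        wanted = set(labels)
        return np.array([i for i, s in enumerate(self.state_label) if s in wanted], dtype=int)

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (self.active_site, self.het_site, self.pcg_site, self.open_fiber, self.ctcf):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(np.ascontiguousarray(self.ctcf_occupancy).tobytes())
        h.update("\x00".join(self.state_label).encode())
        h.update(str(self.bead_size).encode())
        return h.hexdigest()

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bead": np.arange(self.n_beads),
                "start": np.arange(self.n_beads) * self.bead_size,
                "end": (np.arange(self.n_beads) + 1) * self.bead_size,
                "active_site": self.active_site.astype(int),
                "het_site": self.het_site.astype(int),
                "pcg_site": self.pcg_site.astype(int),
                "open_fiber": self.open_fiber.astype(int),
                "ctcf": [_CTCF_STR[int(c)] for c in self.ctcf],
                "ctcf_occupancy": self.ctcf_occupancy,
                "state_label": [s if s else "." for s in self.state_label],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, locus_name: str | None = None) -> "BeadAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"ctcf": str, "state_label": str})
        bead_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if len(df) else BEAD_SIZE
        return cls(
            active_site=df["active_site"].to_numpy(bool),
            het_site=df["het_site"].to_numpy(bool),
            pcg_site=df["pcg_site"].to_numpy(bool),
            open_fiber=df["open_fiber"].to_numpy(bool),
            ctcf=np.array([_CTCF_CODE[c] for c in df["ctcf"]], dtype=np.int8),
            ctcf_occupancy=df["ctcf_occupancy"].to_numpy(float),
            state_label=["" if s == "." else s for s in df["state_label"].fillna(".")],
            bead_size=bead_size,
            locus_name=locus_name or Path(path).stem,
        )


def _bead_coverage(n_beads: int, intervals: Sequence[GenomicInterval], bead_size: int) -> np.ndarray:
    """Base pairs of each bead covered by the (possibly overlapping-merged)
    union of intervals."""
    cov = np.zeros(n_beads, dtype=np.int64)
    # merge first so overlapping intervals do not double count
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    L = n_beads * bead_size
    for s, e in merged:
        s, e = max(0, s), min(L, e)
        if s >= e:
            continue
        b0, b1 = s // bead_size, (e - 1) // bead_size
        for b in range(b0, b1 + 1):
            lo = max(s, b * bead_size)
            hi = min(e, (b + 1) * bead_size)
            cov[b] += hi - lo
    return cov


def annotate_beads(
    build: LocusBuild,
    dhs: Sequence[GenomicInterval],
    ctcf: Sequence[GenomicInterval],
    states: Sequence[GenomicInterval],
    state_rules: Mapping[str, str],
    bead_size: int = BEAD_SIZE,
    state_min_fraction: float = 0.5,
    score_normalization: str = "max",
) -> BeadAnnotation:
    """Derive per-bead polymer properties from tracks in simulated coordinates.

    Parameters
    ----------
    build
        The locus build the tracks were lifted onto; fixes the bead count
        ``ceil(length / bead_size)``.
    dhs, ctcf, states
        Lifted tracks (simulated coordinates). DHSs mark active-binder beads
        on any overlap (>= 1 bp); states act by majority coverage
        (``state_min_fraction`` of the bead, default 0.5).
    state_rules
        Maps every state label occurring in ``states`` to one of
        ``{"active_open", "het", "pcg", "neutral"}``. Unknown labels raise.
    score_normalization
        ``"max"`` divides CTCF scores by the locus maximum (occupancy 1 for
        the strongest site); ``"unit"`` takes scores as occupancies already
        in [0, 1]. Sites with score 0 get occupancy 1 under ``"max"`` with
        no scored site present, else their normalized value.
    """
    unknown = sorted({iv.label for iv in states} - set(state_rules))
    if unknown:
        raise ValueError(f"state labels missing from state_rules: {unknown}")
    bad = sorted(set(state_rules.values()) - set(STATE_CATEGORIES))
    if bad:
        raise ValueError(f"state_rules values must be in {STATE_CATEGORIES}, got {bad}")

    n_beads = -(-build.length // bead_size)
    threshold = state_min_fraction * bead_size

    active = _bead_coverage(n_beads, dhs, bead_size) >= 1
    by_cat: dict[str, list[GenomicInterval]] = {c: [] for c in STATE_CATEGORIES}
    for iv in states:
        by_cat[state_rules[iv.label]].append(iv)
    het = _bead_coverage(n_beads, by_cat["het"], bead_size) >= threshold
    pcg = _bead_coverage(n_beads, by_cat["pcg"], bead_size) >= threshold
    open_fiber = _bead_coverage(n_beads, by_cat["active_open"], bead_size) >= threshold

    # dominant state label per bead (ties broken by label sort for determinism)
    label_cov: dict[str, np.ndarray] = {}
    for lab in sorted({iv.label for iv in states}):
        label_cov[lab] = _bead_coverage(
            n_beads, [iv for iv in states if iv.label == lab], bead_size
        )
    state_label = [""] * n_beads
    for b in range(n_beads):
        best, best_cov = "", 0
        for lab in sorted(label_cov):
            c = int(label_cov[lab][b])
            if c > best_cov:
                best, best_cov = lab, c
        state_label[b] = best

    # CTCF: strongest overlapping site per bead; opposite orientations -> both
    ctcf_code = np.zeros(n_beads, dtype=np.int8)
    occ = np.zeros(n_beads, dtype=float)
    if ctcf:
        max_score = max(iv.score for iv in ctcf)
        for iv in sorted(ctcf, key=lambda x: (x.start, x.end, x.orientation)):
            if score_normalization == "unit":
                site_occ = min(1.0, iv.score)
            else:
                site_occ = iv.score / max_score if max_score > 0 else 1.0
            code = CTCF_PLUS if iv.orientation == "+" else CTCF_MINUS
            b0 = max(0, iv.start // bead_size)
            b1 = min(n_beads - 1, (iv.end - 1) // bead_size)
            for b in range(b0, b1 + 1):
                if ctcf_code[b] == CTCF_NONE:
                    ctcf_code[b] = code
                    occ[b] = site_occ
                elif ctcf_code[b] == code or ctcf_code[b] == CTCF_BOTH:
                    occ[b] = max(occ[b], site_occ)
                    if ctcf_code[b] == CTCF_BOTH:
                        pass
                else:  # opposite orientations share the bead
                    ctcf_code[b] = CTCF_BOTH
                    occ[b] = max(occ[b], site_occ)

    return BeadAnnotation(
        active_site=active,
        het_site=het,
        pcg_site=pcg,
        open_fiber=open_fiber,
        ctcf=ctcf_code,
        ctcf_occupancy=occ,
        state_label=state_label,
        bead_size=bead_size,
        locus_name=build.name,
    )
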