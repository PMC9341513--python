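"""Genomic intervals and BED track I/O.

All coordinates are 0-based, half-open (BED convention). Three track kinds
are consumed by the pipeline:

``dhs``
    BED3+ open-chromatin peaks (binding sites for the active bridging
    protein). Optional 4th column is a name, optional 5th a score.
``ctcf``
    BED6 CTCF sites. The strand column is mandatory and gives the motif
    orientation used to gate loop extrusion; the score column gives peak
    strength (used for anchor occupancy).
``states``
    4-column chromatin-state segmentation (chrom, start, end, state label),
    ChromHMM-dense style. Extra columns are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["GenomicInterval", "read_bed", "write_bed", "BedParseError", "TRACK_KINDS"]

TRACK_KINDS = ("dhs", "ctcf", "states")

_VALID_ORIENT = ("+", "-", "none")


class BedParseError(ValueError):
    """A BED line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, lineno=None):
        loc = f"{path}:{lineno}: " if path is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on a chromosome.

    ``orientation`` is "+"/"-" for CTCF motifs and "none" otherwise.
    ``label`` holds the chromatin-state name or peak id; ``score`` the peak
    strength (non-negative; 0.0 when absent).
    """

    chrom: str
    start: int
    end: int
    label: str = ""
    orientation: str = "none"
    score: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.orientation not in _VALID_ORIENT:
            raise ValueError(f"orientation must be one of {_VALID_ORIENT}")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def _parse_line(fields: Sequence[str], kind: str, path, lineno) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(f"expected >=3 columns, got {len(fields)}", path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"non-integer coordinates: {exc}", path, lineno)
    label = ""
    orientation = "none"
    score = 0.0
    if kind == "states":
        if len(fields) < 4:
            raise BedParseError("state segmentation needs a 4th label column", path, lineno)
        label = fields[3]
    elif kind == "ctcf":
        if len(fields) < 6:
            raise BedParseError("CTCF track must be BED6 (strand column mandatory)", path, lineno)
        label = fields[3]
        try:
            score = float(fields[4]) if fields[4] not in (".", "") else 0.0
        except ValueError as exc:
            raise BedParseError(f"bad score: {exc}", path, lineno)
        strand = fields[5]
        if strand not in ("+", "-"):
            raise BedParseError(f"CTCF strand must be '+' or '-', got {strand!r}", path, lineno)
        orientation = strand
    else:  # dhs
        if len(fields) >= 4:
            label = fields[3]
        if len(fields) >= 5 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"bad score: {exc}", path, lineno)
    try:
        return GenomicInterval(chrom, start, end, label=label, orientation=orientation, score=score)
    except ValueError as exc:
        raise BedParseError(str(exc), path, lineno)


def read_bed(path, kind: str) -> list[GenomicInterval]:
    """Read a BED track of the given kind, sorted by (chrom, start).

    Parameters
    ----------
    path : str or Path
        BED3+ file; ``#``-comment, ``track`` and ``browser`` lines are skipped.
    kind : {"dhs", "ctcf", "states"}
        Controls which extra columns are required (see module docstring).
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"kind must be one of {TRACK_KINDS}, got {kind!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_line(line.split("\t"), kind, path, lineno))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (name, score, strand columns always emitted)."""
    with open(path, "w") as fh:
        for iv in intervals:
            strand = iv.orientation if iv.orientation != "none" else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t{iv.score:g}\t{strand}\n"
            )
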