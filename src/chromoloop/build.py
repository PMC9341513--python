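"""Locus builds: ordered reference segments composing a (rearranged) simulated locus.

A ``LocusBuild`` is the in-silico analogue of a custom genome build: an
ordered list of reference segments, each taken forward ("+") or
reverse-complemented ("-"), concatenated into one simulated coordinate
system starting at 0. Enhancer insertions, deletions and reciprocal
translocations are all expressed this way, after which 1D tracks are
lifted into simulated coordinates with :func:`lift_track`.

Coordinate conventions (0-based, half-open throughout):

* segment ``k`` occupies simulated interval ``[offset_k, offset_k + len_k)``
  where ``offset_k = sum(len_j for j < k)``;
* on a "+" segment, simulated base ``offset + i`` is reference base
  ``start + i``;
* on a "-" segment, simulated base ``offset + i`` is reference base
  ``end - 1 - i`` (coordinates are reflected), and interval orientations
  flip ("+" <-> "-").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import GenomicInterval

__all__ = [
    "SourceSegment",
    "LocusBuild",
    "LiftReport",
    "compose_build",
    "lift_track",
    "read_build_spec",
    "write_build_spec",
]


@dataclass(frozen=True)
class SourceSegment:
    """A reference interval with the strand in which it enters the build."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start must be < end, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError("negative segment start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LocusBuild:
    """An ordered, immutable composition of reference segments."""

    segments: tuple[SourceSegment, ...]
    name: str = "build"

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a build needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def length(self) -> int:
        """Total simulated length in bp."""
        return sum(len(s) for s in self.segments)

    @property
    def offsets(self) -> tuple[int, ...]:
        """Simulated start coordinate of each segment."""
        out, acc = [], 0
        for seg in self.segments:
            out.append(acc)
            acc += len(seg)
        return tuple(out)

    def sim_to_ref(self, pos: int) -> tuple[str, int]:
        """Map one simulated base to its (chrom, reference position)."""
        if not 0 <= pos < self.length:
            raise ValueError(f"simulated position {pos} outside locus [0, {self.length})")
        for off, seg in zip(self.offsets, self.segments):
            if off <= pos < off + len(seg):
                i = pos - off
                if seg.strand == "+":
                    return seg.chrom, seg.start + i
                return seg.chrom, seg.end - 1 - i
        raise AssertionError("unreachable")

    def ref_to_sim(self, chrom: str, pos: int) -> list[int]:
        """All simulated positions covering one reference base (may be several
        if segments overlap, empty if the base is not in the build)."""
        hits = []
        for off, seg in zip(self.offsets, self.segments):
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                if seg.strand == "+":
                    hits.append(off + (pos - seg.start))
                else:
                    hits.append(off + (seg.end - 1 - pos))
        return hits


def compose_build(segments: Sequence[SourceSegment], name: str = "build") -> LocusBuild:
    """Validate and assemble segments into a :class:`LocusBuild`."""
    if not segments:
        raise ValueError("cannot compose an empty build")
    return LocusBuild(tuple(segments), name=name)


@dataclass
class LiftReport:
    """Bookkeeping from a liftover: silent interval loss is unacceptable in a
    rearrangement tool, so drops and breakpoint clips are counted."""

    n_input: int = 0
    n_output: int = 0
    n_dropped: int = 0
    n_clipped: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_dropped": self.n_dropped,
            "n_clipped": self.n_clipped,
        }


def _flip(orientation: str) -> str:
    return {"+": "-", "-": "+"}.get(orientation, orientation)


def lift_track(
    intervals: Iterable[GenomicInterval], build: LocusBuild
) -> tuple[list[GenomicInterval], LiftReport]:
    """Lift reference-coordinate intervals into the build's simulated coordinates.

    Each interval is intersected with every segment; the overlapping part is
    clipped to the segment and mapped. On "-" segments coordinates are
    reflected and orientations flipped. Intervals outside all segments are
    dropped (counted in the report); an interval straddling a breakpoint
    yields one clipped piece per side. Output uses chromosome name
    ``build.name`` and is sorted by simulated start.
    """
    report = LiftReport()
    out: list[GenomicInterval] = []
    segs = list(zip(build.offsets, build.segments))
    for iv in intervals:
        report.n_input += 1
        pieces = 0
        for off, seg in segs:
            if seg.chrom != iv.chrom:
                continue
            a = max(iv.start, seg.start)
            b = min(iv.end, seg.end)
            if a >= b:
                continue
            if seg.strand == "+":
                new_start = off + (a - seg.start)
                new_end = off + (b - seg.start)
                orientation = iv.orientation
            else:
                new_start = off + (seg.end - b)
                new_end = off + (seg.end - a)
                orientation = _flip(iv.orientation)
            out.append(
                replace(
                    iv,
                    chrom=build.name,
                    start=new_start,
                    end=new_end,
                    orientation=orientation,
                )
            )
            pieces += 1
            if (a, b) != (iv.start, iv.end):
                report.n_clipped += 1
        if pieces == 0:
            report.n_dropped += 1
        report.n_output += pieces
    out.sort(key=lambda x: (x.start, x.end))
    return out, report


def read_build_spec(path) -> LocusBuild:
    """Read a build spec: tab- or whitespace-separated rows
    ``chrom start end strand``, ``#`` comments allowed; an optional first
    line ``name <build-name>`` names the build."""
    path = Path(path)
    name = path.stem
    segments: list[SourceSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "name" and len(fields) == 2:
                name = fields[1]
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'chrom start end strand'")
            segments.append(
                SourceSegment(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return compose_build(segments, name=name)


def write_build_spec(build: LocusBuild, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"name {build.name}\n")
        for seg in build.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.strand}\n")
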