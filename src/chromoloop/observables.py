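"""Ensemble observables: simulated Hi-C, virtual 4C, TAD calls, geometry,
and structure-based expression proxies.

Every conformation in the ensemble (each snapshot of each polymer copy) is
treated as one cell of the simulated population. Two beads are "in
contact" when their centres are within ``cutoff`` (default 3.5 sigma);
Hi-C and 4C share this definition so that a one-bead-bin contact-map row
equals the 4C profile from the same viewpoint.

Physical units: lengths are in sigma; one sigma corresponds to roughly
21.8 nm of chromatin fiber, so sigma^3 ~= 1.04e-5 um^3 (see
:func:`sigma_cubed_um3`), which converts simulated probe volumes to the
scale of FISH measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.stats import pearsonr

from .annotate import BeadAnnotation
from .engine import Ensemble

__all__ = [
    "ContactMap",
    "FourCProfile",
    "BoundaryCall",
    "GeometryResult",
    "contact_map",
    "virtual_4c",
    "insulation_score",
    "directionality_index",
    "insulation_and_boundaries",
    "compare_maps",
    "radius_of_gyration",
    "probe_volume",
    "bound_fraction",
    "enhancer_contact_fraction",
    "promoter_interval",
    "sigma_nm",
    "sigma_cubed_um3",
]

DEFAULT_CUTOFF = 3.5  # sigma
DEFAULT_BIN_SIZE = 10_000  # bp
sigma_nm = 21.8  # nm of chromatin per simulation length unit


def sigma_cubed_um3(nm: float = sigma_nm) -> float:
    """Volume of one cubic simulation length unit, in cubic micrometres."""
    return (nm * 1e-3) ** 3


# ---------------------------------------------------------------------------
# contact maps


@dataclass
class ContactMap:
    """Binned symmetric contact-frequency matrix (simulated Hi-C)."""

    matrix: np.ndarray  # (B, B), mean contacts per conformation
    bin_size: int  # bp
    bead_size: int = 1000
    origin: int = 0  # bp, simulated coordinates
    locus_name: str = "locus"
    mask: np.ndarray | None = None  # bool, True = unmappable bin

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def masked(self, mask: np.ndarray) -> "ContactMap":
        """Propagate an unmappable-bin mask (rows+columns set to NaN)."""
        m = self.matrix.copy()
        m[mask, :] = np.nan
        m[:, mask] = np.nan
        return ContactMap(np.where(np.isnan(m), np.nan, m), self.bin_size,
                          self.bead_size, self.origin, self.locus_name, mask)

    def to_tsv(self, path) -> None:
        header = "\t".join(str(b * self.bin_size + self.origin) for b in range(self.n_bins))
        np.savetxt(path, self.matrix, delimiter="\t", header=header, fmt="%.6g")

    @classmethod
    def from_tsv(cls, path, bin_size: int, **kw) -> "ContactMap":
        return cls(np.loadtxt(path, delimiter="\t"), bin_size, **kw)


def contact_map(ensemble: Ensemble, bin_size: int = DEFAULT_BIN_SIZE,
                cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Pool bead-pair contacts over all conformations into a binned map.

    The entry (p, q) is the mean number of contacting bead pairs between
    bins p and q per conformation (so one-bead bins give the fraction of
    conformations in contact). Symmetric by construction; self-contacts of
    a bead count on the diagonal.
    """
    bead_size = ensemble.annotation.bead_size
    if bin_size < bead_size:
        raise ValueError(f"bin_size {bin_size} smaller than bead size {bead_size}")
    n = ensemble.n_beads
    bead_bin = (np.arange(n) * bead_size) // bin_size
    B = int(bead_bin[-1]) + 1
    counts = np.zeros((B, B))
    for P in ensemble.iter_conformations():
        tree = cKDTree(P)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            bi = bead_bin[pairs[:, 0]]
            bj = bead_bin[pairs[:, 1]]
            np.add.at(counts, (bi, bj), 1.0)
            np.add.at(counts, (bj, bi), 1.0)
        np.add.at(counts, (bead_bin, bead_bin), 1.0)  # self-contacts
    counts /= ensemble.n_samples
    return ContactMap(counts, bin_size, bead_size, locus_name=ensemble.annotation.locus_name)


@dataclass
class FourCProfile:
    """Virtual 4C: per-bin fraction of conformations contacting a viewpoint."""

    viewpoint: tuple[int, int]  # bp interval, simulated coordinates
    frequencies: np.ndarray  # (B,) in [0, 1]
    bin_size: int
    viewpoint_bins: np.ndarray  # bool flags

    def __post_init__(self):
        f = self.frequencies
        if np.any((f < 0) | (f > 1)):
            raise ValueError("4C frequencies must lie in [0, 1]")

    def to_bedgraph(self, path, chrom: str = "locus") -> None:
        with open(path, "w") as fh:
            for b, v in enumerate(self.frequencies):
                fh.write(f"{chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}\t{v:.6g}\n")


def _interval_beads(interval: tuple[int, int], n_beads: int, bead_size: int) -> np.ndarray:
    start, end = interval
    if start >= end:
        raise ValueError("interval start must be < end")
    b0 = max(0, start // bead_size)
    b1 = min(n_beads, -(-end // bead_size))
    if b0 >= b1:
        raise ValueError(f"interval [{start}, {end}) maps to no bead in the locus")
    return np.arange(b0, b1)


def virtual_4c(ensemble: Ensemble, viewpoint: tuple[int, int],
               cutoff: float = DEFAULT_CUTOFF, bin_size: int | None = None) -> FourCProfile:
    """Fraction of conformations where any viewpoint bead contacts each bin."""
    bead_size = ensemble.annotation.bead_size
    if bin_size is None:
        bin_size = bead_size
    n = ensemble.n_beads
    if not (0 <= viewpoint[0] < n * bead_size):
        raise ValueError(f"viewpoint {viewpoint} outside locus")
    vp = _interval_beads(viewpoint, n, bead_size)
    bead_bin = (np.arange(n) * bead_size) // bin_size
    B = int(bead_bin[-1]) + 1
    hits = np.zeros(B)
    for P in ensemble.iter_conformations():
        d = np.linalg.norm(P[:, None, :] - P[None, vp, :], axis=2)
        in_contact = (d <= cutoff).any(axis=1)
        hit_bins = np.unique(bead_bin[in_contact])
        hits[hit_bins] += 1
    freq = hits / ensemble.n_samples
    vp_bins = np.zeros(B, dtype=bool)
    vp_bins[np.unique(bead_bin[vp])] = True
    return FourCProfile((int(viewpoint[0]), int(viewpoint[1])), freq, bin_size, vp_bins)


def promoter_interval(tss: int, strand: str, size: int = 1000) -> tuple[int, int]:
    """The promoter is the 1-kbp region immediately upstream of the TSS."""
    if strand == "+":
        return (tss - size, tss)
    if strand == "-":
        return (tss, tss + size)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


# ---------------------------------------------------------------------------
# TAD calling


@dataclass
class BoundaryCall:
    """Insulation-based boundary calls with per-window diagnostics."""

    boundaries: np.ndarray  # bp positions (bin starts)
    insulation: np.ndarray  # (B,) consensus-window insulation score
    directionality: np.ndarray  # (B,) directionality index
    windows: tuple[int, ...]
    bin_size: int

    @property
    def boundary_bins(self) -> np.ndarray:
        return self.boundaries // self.bin_size

    def to_bed(self, path, chrom: str = "locus") -> None:
        with open(path, "w") as fh:
            for p in self.boundaries:
                fh.write(f"{chrom}\t{p}\t{p + self.bin_size}\tboundary\n")


def insulation_score(matrix: np.ndarray, window: int) -> np.ndarray:
    """Mean contact frequency in the sliding diamond of half-width ``window``.

    Bins whose diamond falls off the map edge get NaN.
    """
    B = matrix.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= B:
        raise ValueError(f"window {window} too large for a {B}-bin map")
    score = np.full(B, np.nan)
    for i in range(window, B - window):
        block = matrix[i - window : i, i + 1 : i + 1 + window]
        score[i] = np.nanmean(block)
    return score


def directionality_index(matrix: np.ndarray, window: int) -> np.ndarray:
    """Standard directionality index from up/downstream contact imbalance."""
    B = matrix.shape[0]
    di = np.zeros(B)
    for i in range(B):
        lo = max(0, i - window)
        hi = min(B, i + 1 + window)
        A = float(np.nansum(matrix[i, lo:i]))
        Bv = float(np.nansum(matrix[i, i + 1 : hi]))
        E = (A + Bv) / 2.0
        if E <= 0 or A == Bv:
            continue
        di[i] = np.sign(Bv - A) * ((A - E) ** 2 / E + (Bv - E) ** 2 / E)
    return di


def _minima_boundaries(score: np.ndarray, depth: float) -> list[int]:
    """Local minima of the log2-normalized insulation score with prominence
    at least ``depth`` (log2 units); prominence suppresses shallow noise
    dips while keeping genuine insulation valleys."""
    from scipy.signal import find_peaks

    ok = np.isfinite(score) & (score > 0)
    if ok.sum() < 3:
        return []
    ls = np.full_like(score, np.nan)
    ls[ok] = np.log2(score[ok] / np.mean(score[ok]))
    filled = np.where(np.isfinite(ls), ls, np.nanmax(ls))
    peaks, _ = find_peaks(-filled, prominence=depth)
    return [int(p) for p in peaks if ok[p]]


def insulation_and_boundaries(cmap: ContactMap, window: int | None = None,
                              windows: tuple[int, ...] = (3, 4, 5),
                              depth: float = 0.4) -> BoundaryCall:
    """Call TAD boundaries as consensus insulation-score minima.

    Boundaries are prominent local minima (>= ``depth`` log2 units) of the
    diamond insulation score, computed for each window in ``windows`` (or
    only ``window`` when given); positions found by a majority of windows
    (clustered within +/-1 bin) are reported.
    """
    if window is not None:
        windows = (int(window),)
    per_window: list[list[int]] = []
    scores = []
    for w in windows:
        s = insulation_score(cmap.matrix, w)
        scores.append(s)
        per_window.append(_minima_boundaries(s, depth))
    # cluster candidate bins within +/-1 and keep majority-supported clusters
    votes: dict[int, int] = {}
    for cand in per_window:
        for b in cand:
            key = None
            for k in votes:
                if abs(k - b) <= 1:
                    key = k
                    break
            votes[key if key is not None else b] = votes.get(key if key is not None else b, 0) + 1
    need = (len(windows) // 2) + 1
    bins = sorted(k for k, v in votes.items() if v >= need)
    stacked = np.vstack(scores)
    with np.errstate(invalid="ignore"):
        counts = np.sum(np.isfinite(stacked), axis=0)
        consensus = np.where(counts > 0, np.nansum(stacked, axis=0) / np.maximum(counts, 1), np.nan)
    di = directionality_index(cmap.matrix, max(windows))
    return BoundaryCall(
        boundaries=np.array(bins, dtype=int) * cmap.bin_size,
        insulation=consensus,
        directionality=di,
        windows=tuple(windows),
        bin_size=cmap.bin_size,
    )


# ---------------------------------------------------------------------------
# map comparison


def _stratified_pearson(a: np.ndarray, b: np.ndarray, max_sep: int | None = None) -> float:
    """Mean over genomic separations of the Pearson correlation of log
    frequencies at that separation (pseudocount 1e-6)."""
    B = a.shape[0]
    if max_sep is None:
        max_sep = B - 2
    rs = []
    for s in range(1, max_sep + 1):
        x = np.array([a[i, i + s] for i in range(B - s)])
        y = np.array([b[i, i + s] for i in range(B - s)])
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            continue
        lx, ly = np.log(x[ok] + 1e-6), np.log(y[ok] + 1e-6)
        if np.std(lx) < 1e-12 or np.std(ly) < 1e-12:  # constant stratum
            continue
        rs.append(pearsonr(lx, ly)[0])
    return float(np.mean(rs)) if rs else float("nan")


def compare_maps(a: ContactMap, b: ContactMap, di_window: int = 5,
                 boundary_tolerance_bins: int = 2) -> dict:
    """Compare two contact maps the way a simulated map is validated
    against an experimental one.

    Returns directionality-index Pearson correlation, distance-stratified
    Pearson of log frequencies, and the fraction of ``a``'s boundaries with
    a boundary of ``b`` within the tolerance. Masked (NaN) bins must match
    and are excluded.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("bin sizes differ")
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("map shapes differ after masking")
    di_a = directionality_index(a.matrix, di_window)
    di_b = directionality_index(b.matrix, di_window)
    ok = np.isfinite(di_a) & np.isfinite(di_b)
    if np.std(di_a[ok]) > 0 and np.std(di_b[ok]) > 0:
        di_r = float(pearsonr(di_a[ok], di_b[ok])[0])
    else:
        di_r = float("nan")
    strat = _stratified_pearson(a.matrix, b.matrix)
    ba = insulation_and_boundaries(a).boundary_bins
    bb = insulation_and_boundaries(b).boundary_bins
    if len(ba):
        hit = sum(1 for x in ba if len(bb) and np.min(np.abs(bb - x)) <= boundary_tolerance_bins)
        overlap = hit / len(ba)
    else:
        overlap = float("nan")
    return {
        "di_pearson": di_r,
        "stratified_pearson": strat,
        "boundary_overlap": overlap,
    }


# ---------------------------------------------------------------------------
# geometry


@dataclass
class GeometryResult:
    """Per-conformation values of a geometric observable for one interval."""

    values: np.ndarray
    interval: tuple[int, int]
    kind: str  # "rg" (sigma) or "volume" (sigma^3)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def in_physical_units(self) -> np.ndarray:
        """Convert to nm (rg) or um^3 (volume) via sigma ~= 21.8 nm."""
        if self.kind == "rg":
            return self.values * sigma_nm
        return self.values * sigma_cubed_um3()


def radius_of_gyration(positions: np.ndarray, interval: tuple[int, int] | None = None,
                       bead_size: int = 1000) -> float:
    """Root-mean-square distance of the interval's beads from their centroid."""
    P = positions
    if interval is not None:
        beads = _interval_beads(interval, len(positions), bead_size)
        P = positions[beads]
    if len(P) == 0:
        raise ValueError("empty bead set")
    c = P.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((P - c) ** 2, axis=1))))


def probe_volume(positions: np.ndarray, interval: tuple[int, int] | None = None,
                 bead_size: int = 1000, inflation: float = 0.5) -> float:
    """Occupied volume of a probe region: convex hull of the member beads,
    inflated by one bead radius.

    The inflation approximates the Minkowski sum of the hull with a ball of
    radius ``inflation``: V + A*r + 4/3 pi r^3, with exact lower-dimensional
    fallbacks for coplanar / collinear / single-point bead sets (slab,
    capsule, sphere). This mimics what a FISH probe signal occupies rather
    than a gyration-based size.
    """
    P = positions
    if interval is not None:
        beads = _interval_beads(interval, len(positions), bead_size)
        P = positions[beads]
    if len(P) == 0:
        raise ValueError("empty bead set")
    r = inflation
    sphere = 4.0 / 3.0 * np.pi * r**3
    if len(P) >= 4:
        try:
            hull = ConvexHull(P)
            return float(hull.volume + hull.area * r + sphere)
        except QhullError:
            pass  # degenerate: fall through to planar / linear handling
    # planar or worse: project onto principal components
    c = P.mean(axis=0)
    Q = P - c
    _, s, vt = np.linalg.svd(Q, full_matrices=False)
    rank = int(np.sum(s > 1e-9))
    if rank >= 2:
        XY = Q @ vt[:2].T
        try:
            hull2 = ConvexHull(XY)
            area, perim = hull2.volume, hull2.area  # 2D: volume=area, area=perimeter
            return float(2 * r * area + 0.5 * np.pi * r**2 * perim + sphere)
        except QhullError:
            rank = 1
    if rank == 1:
        t = Q @ vt[0]
        L = float(t.max() - t.min())
        return float(np.pi * r**2 * L + sphere)
    return float(sphere)


def geometry_over_ensemble(ensemble: Ensemble, interval: tuple[int, int],
                           kind: str = "rg", inflation: float | None = None) -> GeometryResult:
    """Evaluate rg or probe volume for every conformation of the ensemble."""
    bead_size = ensemble.annotation.bead_size
    vals = []
    for P in ensemble.iter_conformations():
        if kind == "rg":
            vals.append(radius_of_gyration(P, interval, bead_size))
        elif kind == "volume":
            infl = 0.5 if inflation is None else inflation
            vals.append(probe_volume(P, interval, bead_size, inflation=infl))
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")
    return GeometryResult(np.array(vals), tuple(interval), kind)


# ---------------------------------------------------------------------------
# expression proxies


def bound_fraction(ensemble: Ensemble, promoter: tuple[int, int],
                   capture_radius: float = DEFAULT_CUTOFF) -> float:
    """Fraction of conformations where an active, binding-competent protein
    sits within ``capture_radius`` of any promoter bead."""
    if ensemble.protein_pos.shape[1] == 0:
        raise ValueError("ensemble has no protein records")
    bead_size = ensemble.annotation.bead_size
    pb = _interval_beads(promoter, ensemble.n_beads, bead_size)
    active = ensemble.protein_species == 0
    if not active.any():
        return 0.0
    hits = 0
    for s in range(ensemble.n_snapshots):
        prot = ensemble.protein_pos[s][active & ensemble.protein_on[s]]
        for c in range(ensemble.n_copies):
            if len(prot) == 0:
                continue
            P = ensemble.bead_pos[s, c][pb]
            d = np.linalg.norm(P[:, None, :] - prot[None, :, :], axis=2)
            if (d <= capture_radius).any():
                hits += 1
    return hits / ensemble.n_samples


def enhancer_contact_fraction(ensemble: Ensemble, promoter: tuple[int, int],
                              enhancer_beads: np.ndarray,
                              cutoff: float = DEFAULT_CUTOFF) -> float:
    """Fraction of conformations where the promoter loops to enhancer-state
    chromatin (any promoter bead within ``cutoff`` of any enhancer bead).

    ``enhancer_beads`` typically comes from
    ``annotation.beads_with_state(enhancer_labels)``; promoter beads are
    excluded from the enhancer set. An empty enhancer set is an error — a
    fraction of zero means "never close", not "nothing to be close to".
    """
    bead_size = ensemble.annotation.bead_size
    pb = _interval_beads(promoter, ensemble.n_beads, bead_size)
    enh = np.setdiff1d(np.asarray(enhancer_beads, dtype=int), pb)
    if len(enh) == 0:
        raise ValueError("empty enhancer bead set (after excluding promoter beads)")
    hits = 0
    for s in range(ensemble.n_snapshots):
        for c in range(ensemble.n_copies):
            P = ensemble.bead_pos[s, c]
            d = np.linalg.norm(P[pb][:, None, :] - P[enh][None, :, :], axis=2)
            if (d <= cutoff).any():
                hits += 1
    return hits / ensemble.n_samples
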