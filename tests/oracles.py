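"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the code paths (KD-trees, vectorized binning,
convex-hull inflation helper) used by the package so that agreement is a
genuine cross-check.
"""

import numpy as np


def contact_map_bruteforce(ensemble, bin_size, cutoff):
    """O(N^2) per-snapshot double loop, counting bead-pair contacts per bin."""
    bead_size = ensemble.annotation.bead_size
    n = ensemble.n_beads
    B = ((n - 1) * bead_size) // bin_size + 1
    counts = np.zeros((B, B))
    for P in ensemble.iter_conformations():
        for i in range(n):
            bi = (i * bead_size) // bin_size
            counts[bi, bi] += 1.0  # self contact
            for j in range(i + 1, n):
                d = np.sqrt(np.sum((P[i] - P[j]) ** 2))
                if d <= cutoff:
                    bj = (j * bead_size) // bin_size
                    counts[bi, bj] += 1.0
                    counts[bj, bi] += 1.0
    return counts / ensemble.n_samples


def virtual_4c_bruteforce(ensemble, viewpoint, cutoff, bin_size):
    bead_size = ensemble.annotation.bead_size
    n = ensemble.n_beads
    vp = [b for b in range(n)
          if b * bead_size < viewpoint[1] and (b + 1) * bead_size > viewpoint[0]]
    B = ((n - 1) * bead_size) // bin_size + 1
    hits = np.zeros(B)
    for P in ensemble.iter_conformations():
        seen = set()
        for b in range(n):
            for v in vp:
                if np.sqrt(np.sum((P[b] - P[v]) ** 2)) <= cutoff:
                    seen.add((b * bead_size) // bin_size)
                    break
        for k in seen:
            hits[k] += 1
    return hits / ensemble.n_samples


def rg_bruteforce(P):
    """Pair-distance form: Rg^2 = (1/2N^2) sum_ij |r_i - r_j|^2."""
    N = len(P)
    acc = 0.0
    for i in range(N):
        for j in range(N):
            acc += np.sum((P[i] - P[j]) ** 2)
    return np.sqrt(acc / (2 * N * N))


def hull_volume_area_bruteforce(P):
    """Hull volume by Delaunay tetrahedra; area by summing facet triangles."""
    from scipy.spatial import ConvexHull, Delaunay

    tri = Delaunay(P)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = P[simplex]
        vol += abs(np.dot(np.cross(b - a, c - a), d - a)) / 6.0
    hull = ConvexHull(P)
    area = 0.0
    for simplex in hull.simplices:
        a, b, c = P[simplex]
        area += np.linalg.norm(np.cross(b - a, c - a)) / 2.0
    return vol, area


def probe_volume_bruteforce(P, inflation):
    vol, area = hull_volume_area_bruteforce(P)
    return vol + area * inflation + 4.0 / 3.0 * np.pi * inflation**3


def bound_fraction_bruteforce(ensemble, promoter, capture_radius):
    bead_size = ensemble.annotation.bead_size
    n = ensemble.n_beads
    pb = [b for b in range(n)
          if b * bead_size < promoter[1] and (b + 1) * bead_size > promoter[0]]
    hits = 0
    for s in range(ensemble.n_snapshots):
        for c in range(ensemble.n_copies):
            found = False
            for p in range(ensemble.protein_pos.shape[1]):
                if ensemble.protein_species[p] != 0 or not ensemble.protein_on[s, p]:
                    continue
                for b in pb:
                    d = np.sqrt(np.sum(
                        (ensemble.bead_pos[s, c, b] - ensemble.protein_pos[s, p]) ** 2))
                    if d <= capture_radius:
                        found = True
                        break
                if found:
                    break
            hits += found
    return hits / ensemble.n_samples


def extrusion_oracle_1d(n, ctcf, occupancy, unload_prob, n_updates, rng,
                        initial=None, n_extruders=1):
    """Event-free 1D loop extrusion with the same stepping rules as the
    engine but no 3D geometry: left legs blocked (prob = occupancy) while
    sitting on '+'/'both' anchors, right legs on '-'/'both'.

    Returns the (n_updates, n_extruders, 2) leg-position history.
    """
    legs = np.full((n_extruders, 2), -1, dtype=int)
    if initial is not None:
        legs[0] = initial
    occupied = set(int(x) for x in legs.ravel() if x >= 0)
    hist = np.empty((n_updates, n_extruders, 2), dtype=int)
    for t in range(n_updates):
        for k in range(n_extruders):
            if legs[k, 0] >= 0 and rng.random() < unload_prob:
                occupied.discard(legs[k, 0])
                occupied.discard(legs[k, 1])
                legs[k] = (-1, -1)
        for k in range(n_extruders):
            if legs[k, 0] >= 0:
                continue
            for _ in range(20):
                i = int(rng.integers(0, n - 1))
                if i not in occupied and i + 1 not in occupied:
                    legs[k] = (i, i + 1)
                    occupied.update((i, i + 1))
                    break
        for k in range(n_extruders):
            a, b = legs[k]
            if a < 0:
                continue
            if a - 1 >= 0 and a - 1 not in occupied:
                if ctcf[a] in (1, 3) and rng.random() < occupancy[a]:
                    pass
                else:
                    occupied.discard(a)
                    a -= 1
                    occupied.add(a)
                    legs[k, 0] = a
            if b + 1 < n and b + 1 not in occupied:
                if ctcf[b] in (2, 3) and rng.random() < occupancy[b]:
                    pass
                else:
                    occupied.discard(b)
                    b += 1
                    occupied.add(b)
                    legs[k, 1] = b
        hist[t] = legs
    return hist
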