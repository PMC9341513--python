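"""Numba kernels for the Langevin dynamics integrator.

Force field (reduced units, kT = 1, bead mass = 1):

* backbone: stiff harmonic bonds between consecutive beads of a copy,
  rest length = sum of the two bead radii;
* excluded volume: WCA (purely repulsive shifted Lennard-Jones, depth 1)
  between every particle pair, with pair diameter = sum of radii;
* cognate attraction: a binding-competent protein and a bead carrying its
  binding flag interact through a truncated Lennard-Jones well of depth
  eps_species, cutoff 1.8 x pair diameter (replaces WCA for that pair);
* crumpling: compact (non-open) beads of the same copy attract weakly
  (depth eps_compact, same truncated-LJ form);
* bending: cosine angle potential k_bend * (1 - cos theta) applied where
  three consecutive beads are all open fiber;
* extruder coupling: harmonic spring between the two leg beads of each
  loaded extruder;
* confinement: harmonic half-space wall at radius R_conf from the origin
  (nucleus-like sphere).

The integrator is velocity-Verlet-style Langevin with the
Ornstein-Uhlenbeck velocity damping applied exactly
(v <- c1 v + c2 xi, c1 = exp(-gamma dt), c2 = sqrt(kT (1 - c1^2))).
With ``overdamped=True`` inertia is dropped and per-step displacements are
capped at ``max_disp`` — used to anneal away initial overlaps.

All randomness comes from numba's thread-local NumPy legacy RNG, seeded
once per run through :func:`seed_rng`; single-threaded execution is then
bit-reproducible.
"""

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
ATTR_CUT = 1.8  # x pair diameter


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _pair_forces(pos, F, rad, flags, copy_of, n_bead_total,
                 prot_species, prot_on,
                 eps_active, eps_het, eps_pcg, eps_compact, compact_range):
    """Accumulate nonbonded pair forces; returns potential energy."""
    M = pos.shape[0]
    energy = 0.0
    for a in range(M - 1):
        xa, ya, za = pos[a, 0], pos[a, 1], pos[a, 2]
        ra = rad[a]
        for b in range(a + 1, M):
            dx = xa - pos[b, 0]
            dy = ya - pos[b, 1]
            dz = za - pos[b, 2]
            d = ra + rad[b]
            rc_max = ATTR_CUT * d
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_max * rc_max:
                continue
            # decide the pair's attraction depth
            eps = 0.0
            if a < n_bead_total and b < n_bead_total:
                # bonded exclusions: 1-2 and 1-3 neighbours along a chain are
                # governed by their springs (backbone / crumple), not WCA
                if copy_of[a] == copy_of[b] and b - a <= 2:
                    continue
                # bead-bead: compact-fiber crumpling is local — attraction only
                # between compact beads of the same copy within compact_range
                # beads along the chain (keeps distant compact domains from
                # coalescing into one globule)
                if ((flags[a] & 8) == 0 and (flags[b] & 8) == 0
                        and copy_of[a] == copy_of[b] and b - a <= compact_range):
                    eps = eps_compact
            elif a < n_bead_total or b < n_bead_total:
                if a < n_bead_total:
                    g, p = a, b - n_bead_total
                else:
                    g, p = b, a - n_bead_total
                if prot_on[p] == 1:
                    s = prot_species[p]
                    if s == 0 and (flags[g] & 1) != 0:
                        eps = eps_active
                    elif s == 1 and (flags[g] & 2) != 0:
                        eps = eps_het
                    elif s == 2 and (flags[g] & 4) != 0:
                        eps = eps_pcg
            if eps > 0.0:
                rc = ATTR_CUT * d
            else:
                rc = WCA_CUT * d
            if r2 >= rc * rc:
                continue
            inv_r2 = 1.0 / r2
            s2 = d * d * inv_r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            if eps > 0.0:
                fmag = 24.0 * eps * (2.0 * s12 - s6) * inv_r2
                energy += 4.0 * eps * (s12 - s6)
            else:
                fmag = 24.0 * (2.0 * s12 - s6) * inv_r2
                energy += 4.0 * (s12 - s6) + 1.0
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            F[a, 0] += fx
            F[a, 1] += fy
            F[a, 2] += fz
            F[b, 0] -= fx
            F[b, 1] -= fy
            F[b, 2] -= fz
    return energy


@njit(cache=True)
def _bonded_forces(pos, F, rad, n_beads, n_copies, k_bond,
                   open_bead, k_bend, crumple_k,
                   ext_a, ext_b, ext_copy, extruder_k):
    """Backbone bonds, bending along open runs, compact-run crumpling
    springs (second-neighbour harmonic, folds the thick fiber back on
    itself), extruder springs."""
    for c in range(n_copies):
        base = c * n_beads
        for i in range(n_beads - 1):
            g, h = base + i, base + i + 1
            dx = pos[h, 0] - pos[g, 0]
            dy = pos[h, 1] - pos[g, 1]
            dz = pos[h, 2] - pos[g, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-12:
                continue
            r0 = rad[g] + rad[h]
            fmag = k_bond * (r - r0) / r
            F[g, 0] += fmag * dx
            F[g, 1] += fmag * dy
            F[g, 2] += fmag * dz
            F[h, 0] -= fmag * dx
            F[h, 1] -= fmag * dy
            F[h, 2] -= fmag * dz
        if crumple_k > 0.0:
            for i in range(n_beads - 2):
                if open_bead[i] or open_bead[i + 1] or open_bead[i + 2]:
                    continue
                g, h = base + i, base + i + 2
                dx = pos[h, 0] - pos[g, 0]
                dy = pos[h, 1] - pos[g, 1]
                dz = pos[h, 2] - pos[g, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < 1e-12:
                    continue
                r0 = rad[g] + rad[h]  # fold i and i+2 into contact
                fmag = crumple_k * (r - r0) / r
                F[g, 0] += fmag * dx
                F[g, 1] += fmag * dy
                F[g, 2] += fmag * dz
                F[h, 0] -= fmag * dx
                F[h, 1] -= fmag * dy
                F[h, 2] -= fmag * dz
        if k_bend > 0.0:
            for i in range(1, n_beads - 1):
                if not (open_bead[i - 1] and open_bead[i] and open_bead[i + 1]):
                    continue
                g0, g1, g2 = base + i - 1, base + i, base + i + 1
                b1x = pos[g1, 0] - pos[g0, 0]
                b1y = pos[g1, 1] - pos[g0, 1]
                b1z = pos[g1, 2] - pos[g0, 2]
                b2x = pos[g2, 0] - pos[g1, 0]
                b2y = pos[g2, 1] - pos[g1, 1]
                b2z = pos[g2, 2] - pos[g1, 2]
                n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
                n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
                if n1 < 1e-12 or n2 < 1e-12:
                    continue
                u1x, u1y, u1z = b1x / n1, b1y / n1, b1z / n1
                u2x, u2y, u2z = b2x / n2, b2y / n2, b2z / n2
                ct = u1x * u2x + u1y * u2y + u1z * u2z
                # F = k * d(cos theta)/dr  (U = k (1 - cos theta))
                f0x = -k_bend * (u2x - ct * u1x) / n1
                f0y = -k_bend * (u2y - ct * u1y) / n1
                f0z = -k_bend * (u2z - ct * u1z) / n1
                f2x = k_bend * (u1x - ct * u2x) / n2
                f2y = k_bend * (u1y - ct * u2y) / n2
                f2z = k_bend * (u1z - ct * u2z) / n2
                F[g0, 0] += f0x
                F[g0, 1] += f0y
                F[g0, 2] += f0z
                F[g2, 0] += f2x
                F[g2, 1] += f2y
                F[g2, 2] += f2z
                F[g1, 0] -= f0x + f2x
                F[g1, 1] -= f0y + f2y
                F[g1, 2] -= f0z + f2z
    for k in range(ext_a.shape[0]):
        if ext_a[k] < 0:
            continue
        base = ext_copy[k] * n_beads
        g, h = base + ext_a[k], base + ext_b[k]
        dx = pos[h, 0] - pos[g, 0]
        dy = pos[h, 1] - pos[g, 1]
        dz = pos[h, 2] - pos[g, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        r0 = rad[g] + rad[h]
        fmag = extruder_k * (r - r0) / r
        F[g, 0] += fmag * dx
        F[g, 1] += fmag * dy
        F[g, 2] += fmag * dz
        F[h, 0] -= fmag * dx
        F[h, 1] -= fmag * dy
        F[h, 2] -= fmag * dz


@njit(cache=True)
def _wall_forces(pos, F, R_conf, k_wall):
    M = pos.shape[0]
    for a in range(M):
        r = np.sqrt(pos[a, 0] ** 2 + pos[a, 1] ** 2 + pos[a, 2] ** 2)
        if r > R_conf and r > 1e-12:
            fmag = -k_wall * (r - R_conf) / r
            F[a, 0] += fmag * pos[a, 0]
            F[a, 1] += fmag * pos[a, 1]
            F[a, 2] += fmag * pos[a, 2]


@njit(cache=True)
def integrate(pos, vel, rad, flags, copy_of, n_bead_total, n_beads, n_copies,
              open_bead, prot_species, prot_on, ext_a, ext_b, ext_copy,
              n_steps, dt, gamma, kT, k_bond, k_bend, crumple_k,
              eps_active, eps_het, eps_pcg, eps_compact, compact_range, extruder_k,
              R_conf, k_wall, overdamped, max_disp):
    """Advance the system ``n_steps`` Langevin steps in place."""
    M = pos.shape[0]
    F = np.zeros((M, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    for _ in range(n_steps):
        F[:, :] = 0.0
        _pair_forces(pos, F, rad, flags, copy_of, n_bead_total,
                     prot_species, prot_on,
                     eps_active, eps_het, eps_pcg, eps_compact, compact_range)
        _bonded_forces(pos, F, rad, n_beads, n_copies, k_bond,
                       open_bead, k_bend, crumple_k, ext_a, ext_b, ext_copy, extruder_k)
        _wall_forces(pos, F, R_conf, k_wall)
        if overdamped:
            for a in range(M):
                for d in range(3):
                    step = (F[a, d] * dt + np.sqrt(2.0 * kT * dt) * np.random.normal()) / gamma
                    if step > max_disp:
                        step = max_disp
                    elif step < -max_disp:
                        step = -max_disp
                    pos[a, d] += step
                    vel[a, d] = 0.0
        else:
            for a in range(M):
                for d in range(3):
                    v = vel[a, d] + dt * F[a, d]
                    v = c1 * v + c2 * np.random.normal()
                    vel[a, d] = v
                    pos[a, d] += dt * v
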