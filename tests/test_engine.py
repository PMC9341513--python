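import numpy as np
import pytest
from scipy.stats import wilcoxon

from conftest import blank_annotation
from chromoloop import _kernels
from chromoloop.annotate import annotate_beads
from chromoloop.build import lift_track
from chromoloop.engine import (
    init_system,
    run_simulation,
    step_dynamics,
    update_extruders,
)
from chromoloop.fixtures import DEFAULT_STATE_RULES, ToyLocusSpec, make_toy_locus
from chromoloop.params import SimulationParams

BOND_MAX = 2.5  # sigma; generous backbone-extension bound for harmonic bonds


def quick_params(**kw):
    kw.setdefault("n_active", 0)
    kw.setdefault("n_het", 0)
    kw.setdefault("n_pcg", 0)
    kw.setdefault("n_extruders", 0)
    return SimulationParams(**kw)


def max_bond(positions):
    return float(np.linalg.norm(np.diff(positions, axis=0), axis=1).max())


# ---------------------------------------------------------------------------
# initialization


def test_init_single_chain_bond_bounds():
    ann = blank_annotation(100)
    st = init_system(ann, quick_params(seed=1))
    assert st.pos.shape == (100, 3)
    assert max_bond(st.bead_positions(0)) <= BOND_MAX


def test_init_deterministic_given_seed():
    ann = blank_annotation(60)
    p = SimulationParams(seed=9)
    a = init_system(ann, p, np.random.default_rng(9))
    b = init_system(ann, p, np.random.default_rng(9))
    np.testing.assert_array_equal(a.pos, b.pos)


def test_paper_scale_copies_give_forty_thousand_beads():
    # 11 copies of a ~3.64-Mbp locus -> ~40,000 beads in one volume
    ann = blank_annotation(3636)
    st = init_system(ann, quick_params(n_copies=11, seed=0))
    assert st.n_bead_total == 11 * 3636
    assert abs(st.n_bead_total - 40_000) < 50
    for c in (0, 5, 10):
        assert max_bond(st.bead_positions(c)) <= BOND_MAX


def test_overcrowded_density_rejected():
    ann = blank_annotation(5)
    with pytest.raises(ValueError, match="density"):
        init_system(ann, quick_params(box_density=0.49, seed=0))


# ---------------------------------------------------------------------------
# dynamics


def test_dynamics_preserves_connectivity_and_finiteness():
    ann = blank_annotation(50)
    p = quick_params(seed=2)
    st = init_system(ann, p)
    step_dynamics(st, 2000, p, overdamped=True)
    for _ in range(5):
        step_dynamics(st, 500, p)
        assert np.all(np.isfinite(st.pos))
        assert max_bond(st.bead_positions(0)) <= BOND_MAX


def test_strong_protein_stays_bound_to_cognate_bead():
    """A single active protein with binding energy >> kT should sit within
    the attraction cutoff of the single active bead in nearly all late
    snapshots (two-body bound state dominates the Boltzmann weight)."""
    n = 10
    ann = blank_annotation(n)
    ann.active_site[5] = True
    p = SimulationParams(n_active=1, n_het=0, n_pcg=0, n_extruders=0,
                         eps_active=8.0, protein_switch_rate=0.0,
                         n_snapshots=150, snapshot_interval=100, seed=4)
    ens = run_simulation(ann, p)
    cutoff = 1.8 * (0.5 * p.compact_diameter + 0.5 * p.protein_diameter)
    d = np.linalg.norm(ens.bead_pos[:, 0, 5, :] - ens.protein_pos[:, 0, :], axis=1)
    late = d[len(d) // 3:]
    assert np.mean(late <= cutoff) >= 0.9


def test_internal_distances_match_independent_saw_reference():
    """With all couplings off (no proteins, no extruders, homogeneous
    compact fiber, crumpling disabled) the engine is a plain self-avoiding
    chain; its mean-squared internal distances must match an independently
    written reference simulation within 3 combined standard errors."""
    n = 40
    p = quick_params(seed=6, crumple_k=0.0, eps_compact=0.0, n_snapshots=150,
                     snapshot_interval=200, equilibration_steps=10_000)
    ens = run_simulation(blank_annotation(n), p)
    # separations that relax well within the sampling window (the full
    # end-to-end distance of the chain would need a far longer run)
    seps = (3, 5, 8, 12)

    def msid(traj):  # traj: (S, n, 3)
        out = {}
        for s in seps:
            d2 = np.sum((traj[:, s:, :] - traj[:, :-s, :]) ** 2, axis=2)
            per_snap = d2.mean(axis=1)
            out[s] = (per_snap.mean(), per_snap.std(ddof=1))
        return out

    # independent reference: plain NumPy Langevin SAW with the same
    # backbone/WCA/confinement physics, written without the engine kernels
    rng = np.random.default_rng(60)
    d = p.compact_diameter
    R_conf = (n * 0.125 / p.box_density) ** (1 / 3)
    pos = np.zeros((n, 3))
    steps = rng.normal(size=(n - 1, 3))
    steps *= d / np.linalg.norm(steps, axis=1, keepdims=True)
    pos[1:] = np.cumsum(steps, axis=0)
    vel = np.zeros((n, 3))
    dt, gamma = p.dt, p.gamma
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1 - c1**2)
    iu = np.triu_indices(n, 3)  # 1-2 and 1-3 neighbours excluded, as in the engine

    def forces(x):
        F = np.zeros_like(x)
        bond = x[1:] - x[:-1]
        r = np.linalg.norm(bond, axis=1, keepdims=True)
        f = 100.0 * (r - d) * bond / r
        F[:-1] += f
        F[1:] -= f
        diff = x[iu[0]] - x[iu[1]]
        r2 = np.sum(diff**2, axis=1)
        wca = r2 < (2 ** (1 / 6) * d) ** 2
        if wca.any():
            rr2 = r2[wca]
            s6 = (d * d / rr2) ** 3
            fmag = 24.0 * (2 * s6 * s6 - s6) / rr2
            fv = fmag[:, None] * diff[wca]
            np.add.at(F, iu[0][wca], fv)
            np.add.at(F, iu[1][wca], -fv)
        rad = np.linalg.norm(x, axis=1)
        out = rad > R_conf
        if out.any():
            F[out] -= (20.0 * (rad[out] - R_conf) / rad[out])[:, None] * x[out]
        return F

    # displacement-capped warmup then sampling, mirroring the protocol
    for _ in range(2000):
        F = forces(pos)
        disp = (F * dt + np.sqrt(2 * dt) * rng.normal(size=pos.shape)) / gamma
        pos += np.clip(disp, -0.1, 0.1)
    ref = []
    for k in range(10_000 + 150 * 200):
        F = forces(pos)
        vel = c1 * (vel + dt * F) + c2 * rng.normal(size=pos.shape)
        pos += dt * vel
        if k >= 10_000 and (k - 10_000) % 200 == 199:
            ref.append(pos.copy())
    ref = np.array(ref)

    a = msid(ens.bead_pos[:, 0])
    b = msid(ref)
    n_eff = 150 / 10  # conservative: snapshots 100 steps apart are correlated
    for s in seps:
        se = np.sqrt((a[s][1] ** 2 + b[s][1] ** 2) / n_eff)
        assert abs(a[s][0] - b[s][0]) <= 3 * se, (s, a[s], b[s])


# ---------------------------------------------------------------------------
# extrusion


def anchored_annotation(n, plus_at=(), minus_at=()):
    ann = blank_annotation(n)
    for b in plus_at:
        ann.ctcf[b] = 1
        ann.ctcf_occupancy[b] = 1.0
    for b in minus_at:
        ann.ctcf[b] = 2
        ann.ctcf_occupancy[b] = 1.0
    return ann


def loaded_state(ann, params, legs, seed=0):
    rng = np.random.default_rng(seed)
    st = init_system(ann, params, rng)
    st.ext_a[0], st.ext_b[0] = legs
    return st, rng


def test_free_extruder_steps_both_legs_outward():
    ann = blank_annotation(20)
    p = SimulationParams(n_extruders=1, unload_prob=0.0, capture_radius=1e6,
                         n_active=0, n_het=0, n_pcg=0, seed=0)
    st, rng = loaded_state(ann, p, (9, 10))
    update_extruders(st, ann, p, rng)
    assert (st.ext_a[0], st.ext_b[0]) == (8, 11)


def test_plus_anchor_blocks_leftward_passage():
    """Directed test of the blocking convention: a '+' anchor halts
    right-to-left travel, so a left leg sitting on it never moves on."""
    ann = anchored_annotation(20, plus_at=[5])
    p = SimulationParams(n_extruders=1, unload_prob=0.0, capture_radius=1e6,
                         n_active=0, n_het=0, n_pcg=0, seed=0)
    st, rng = loaded_state(ann, p, (6, 10))
    for _ in range(30):
        update_extruders(st, ann, p, rng)
    assert st.ext_a[0] == 5  # stepped onto the anchor, then pinned
    assert st.ext_b[0] == 19
    assert st.block_rejections.get(5, 0) > 0


def test_minus_anchor_blocks_rightward_passage():
    ann = anchored_annotation(20, minus_at=[14])
    p = SimulationParams(n_extruders=1, unload_prob=0.0, capture_radius=1e6,
                         n_active=0, n_het=0, n_pcg=0, seed=0)
    st, rng = loaded_state(ann, p, (10, 12))
    for _ in range(30):
        update_extruders(st, ann, p, rng)
    assert st.ext_b[0] == 14
    assert st.ext_a[0] == 0


def test_unload_prob_one_relocates_every_update():
    ann = blank_annotation(50)
    p = SimulationParams(n_extruders=2, unload_prob=1.0, capture_radius=1e6,
                         n_active=0, n_het=0, n_pcg=0, seed=0)
    rng = np.random.default_rng(3)
    st = init_system(ann, p, rng)
    seen = set()
    for _ in range(30):
        update_extruders(st, ann, p, rng)
        assert (st.ext_a >= 0).all()  # unloaded then immediately reloaded
        assert (st.ext_b - st.ext_a <= 3).all()  # fresh loads step at most once
        seen.update(st.ext_a.tolist())
    assert len(seen) > 5  # genuinely relocating


def test_leg_invariants_over_a_run():
    spec = ToyLocusSpec(n_tads=2, tad_length=50, seed=0)
    build, tracks, _ = make_toy_locus(spec)
    lifted = {k: lift_track(v, build)[0] for k, v in tracks.items()}
    ann = annotate_beads(build, lifted["dhs"], lifted["ctcf"], lifted["states"],
                         DEFAULT_STATE_RULES, score_normalization="unit")
    p = SimulationParams(n_extruders=4, n_snapshots=40, snapshot_interval=50,
                         n_active=0, n_het=0, n_pcg=0, seed=5)
    ens = run_simulation(ann, p)
    for s in range(ens.n_snapshots):
        loaded = ens.extruders[s][ens.extruders[s, :, 1] >= 0]
        assert (loaded[:, 1] < loaded[:, 2]).all()  # i < j always
        for c in np.unique(loaded[:, 0]):
            legs = loaded[loaded[:, 0] == c][:, 1:].ravel()
            assert len(set(legs.tolist())) == len(legs)  # no shared beads


def test_within_tad_contacts_exceed_between_tad_at_equal_separation():
    """Planted-TAD toy locus: contacts at equal genomic separation are
    enriched inside TADs relative to across the boundary (one-sided test
    over the snapshot population)."""
    from scipy.spatial import cKDTree

    spec = ToyLocusSpec(n_tads=2, tad_length=100, seed=0)
    build, tracks, _ = make_toy_locus(spec)
    lifted = {k: lift_track(v, build)[0] for k, v in tracks.items()}
    ann = annotate_beads(build, lifted["dhs"], lifted["ctcf"], lifted["states"],
                         DEFAULT_STATE_RULES, score_normalization="unit")
    p = SimulationParams(n_snapshots=200, n_active=0, n_het=0, n_pcg=0, seed=8)
    ens = run_simulation(ann, p)
    diffs = []
    for P in ens.iter_conformations():
        pairs = cKDTree(P).query_pairs(3.5, output_type="ndarray")
        sep = pairs[:, 1] - pairs[:, 0]
        sel = (sep >= 20) & (sep <= 60)
        within = ((pairs[:, 0] // 100) == (pairs[:, 1] // 100)) & sel
        between = ((pairs[:, 0] // 100) != (pairs[:, 1] // 100)) & sel
        diffs.append(within.sum() - between.sum())
    diffs = np.array(diffs)
    assert diffs.mean() > 0
    assert wilcoxon(diffs, alternative="greater").pvalue < 0.01


# ---------------------------------------------------------------------------
# reproducibility


def test_identical_seed_gives_bit_identical_trajectories():
    ann = blank_annotation(40)
    p = quick_params(n_snapshots=10, snapshot_interval=50, seed=13,
                     n_extruders=1, n_active=2)
    a = run_simulation(ann, p)
    b = run_simulation(ann, p)
    np.testing.assert_array_equal(a.bead_pos, b.bead_pos)
    np.testing.assert_array_equal(a.protein_pos, b.protein_pos)
    np.testing.assert_array_equal(a.extruders, b.extruders)


def test_ensemble_save_load_roundtrip(tmp_path):
    ann = blank_annotation(20)
    p = quick_params(n_snapshots=4, snapshot_interval=50, seed=2, n_active=1)
    ens = run_simulation(ann, p)
    ens.save(tmp_path / "traj")
    back = type(ens).load(tmp_path / "traj")
    np.testing.assert_allclose(back.bead_pos, ens.bead_pos, atol=1e-6)
    np.testing.assert_array_equal(back.protein_on, ens.protein_on)
    assert back.metadata["annotation_checksum"] == ens.metadata["annotation_checksum"]
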