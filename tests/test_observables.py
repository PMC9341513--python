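import numpy as np
import pytest

from conftest import blank_annotation, ensemble_from_positions, random_ensemble
from oracles import (
    bound_fraction_bruteforce,
    contact_map_bruteforce,
    probe_volume_bruteforce,
    rg_bruteforce,
    virtual_4c_bruteforce,
)
from chromoloop.fixtures import make_reference_conformation
from chromoloop.observables import (
    ContactMap,
    bound_fraction,
    compare_maps,
    contact_map,
    directionality_index,
    enhancer_contact_fraction,
    insulation_and_boundaries,
    insulation_score,
    probe_volume,
    promoter_interval,
    radius_of_gyration,
    sigma_cubed_um3,
    virtual_4c,
)


# ---------------------------------------------------------------------------
# contact maps


def test_two_beads_single_contact():
    P = np.array([[0, 0, 0], [2.0, 0, 0]])
    ens = ensemble_from_positions(P)
    cm = contact_map(ens, bin_size=1000, cutoff=3.5)
    assert cm.matrix[0, 1] == 1.0 and cm.matrix[1, 0] == 1.0


def test_straight_chain_contacts_exactly_within_three_beads():
    P = make_reference_conformation("line", 20)
    ens = ensemble_from_positions(P)
    cm = contact_map(ens, bin_size=1000, cutoff=3.5)
    for i in range(20):
        for j in range(20):
            assert cm.matrix[i, j] == (1.0 if abs(i - j) <= 3 else 0.0)


def test_contact_map_symmetric_for_random_ensemble(rng):
    ens = random_ensemble(rng, n_beads=25, n_snapshots=4)
    cm = contact_map(ens, bin_size=5000, cutoff=3.5)
    np.testing.assert_array_equal(cm.matrix, cm.matrix.T)


def test_bin_smaller_than_bead_rejected(rng):
    ens = random_ensemble(rng, n_beads=10)
    with pytest.raises(ValueError, match="bin_size"):
        contact_map(ens, bin_size=500)


def test_contact_map_matches_bruteforce(rng):
    ens = random_ensemble(rng, n_beads=40, n_snapshots=8, n_copies=2, spread=4.0)
    cm = contact_map(ens, bin_size=7000, cutoff=3.5)
    ref = contact_map_bruteforce(ens, 7000, 3.5)
    np.testing.assert_allclose(cm.matrix, ref, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# virtual 4C


def test_4c_zero_when_never_in_cutoff():
    P = make_reference_conformation("line", 30)
    ens = ensemble_from_positions(P)
    prof = virtual_4c(ens, (0, 1000), cutoff=2.0)
    assert prof.frequencies[10] == 0.0
    assert prof.viewpoint_bins[0]


def test_4c_matches_bruteforce_on_toy(rng):
    ens = random_ensemble(rng, n_beads=20, n_snapshots=5, spread=3.0)
    prof = virtual_4c(ens, (8000, 10_000), cutoff=3.5, bin_size=2000)
    ref = virtual_4c_bruteforce(ens, (8000, 10_000), 3.5, 2000)
    np.testing.assert_allclose(prof.frequencies, ref, rtol=1e-9, atol=1e-12)


def test_4c_equals_contact_map_row_at_bead_resolution(rng):
    """One-bead bins make the contact-map row at the viewpoint identical to
    the 4C profile (same cutoff): both are per-conformation indicator means."""
    ens = random_ensemble(rng, n_beads=30, n_snapshots=6, spread=5.0)
    v = 7
    cm = contact_map(ens, bin_size=1000, cutoff=3.5)
    prof = virtual_4c(ens, (v * 1000, (v + 1) * 1000), cutoff=3.5)
    row = cm.matrix[v].copy()
    row[v] = prof.frequencies[v]  # self-bin flagged in the profile
    np.testing.assert_allclose(prof.frequencies, row, rtol=1e-9)


def test_viewpoint_outside_locus_rejected(rng):
    ens = random_ensemble(rng, n_beads=10)
    with pytest.raises(ValueError, match="outside"):
        virtual_4c(ens, (50_000, 51_000))


def test_promoter_is_one_kbp_upstream_of_tss():
    assert promoter_interval(30_000, "+") == (29_000, 30_000)
    assert promoter_interval(30_000, "-") == (30_000, 31_000)
    with pytest.raises(ValueError):
        promoter_interval(30_000, ".")


# ---------------------------------------------------------------------------
# insulation / boundaries / comparison


def block_diagonal_map(B=20, split=10, hi=5.0, lo=0.2):
    m = np.full((B, B), lo)
    m[:split, :split] = hi
    m[split:, split:] = hi
    np.fill_diagonal(m, hi * 2)
    return ContactMap(m, 10_000)


def test_block_diagonal_map_yields_single_boundary_at_junction():
    cm = block_diagonal_map()
    call = insulation_and_boundaries(cm)
    assert len(call.boundaries) == 1
    # the analytic minimum is a two-bin plateau at the junction (bins 9, 10)
    assert call.boundary_bins[0] in (9, 10)


def test_constant_map_has_no_boundaries():
    cm = ContactMap(np.ones((15, 15)), 10_000)
    call = insulation_and_boundaries(cm)
    assert len(call.boundaries) == 0


def test_insulation_window_larger_than_map_rejected():
    with pytest.raises(ValueError, match="window"):
        insulation_score(np.ones((5, 5)), 5)


def test_insulation_diamond_is_mean_of_cross_block():
    m = np.arange(36, dtype=float).reshape(6, 6)
    m = (m + m.T) / 2
    s = insulation_score(m, 2)
    assert s[2] == pytest.approx(np.mean(m[0:2, 3:5]))
    assert np.isnan(s[0]) and np.isnan(s[5])


def test_compare_map_with_itself_gives_unit_correlations():
    cm = block_diagonal_map()
    res = compare_maps(cm, cm)
    assert res["di_pearson"] == pytest.approx(1.0)
    assert res["stratified_pearson"] == pytest.approx(1.0)
    assert res["boundary_overlap"] == 1.0


def test_stratified_pearson_matches_closed_form():
    rng = np.random.default_rng(0)
    a = rng.random((6, 6)) + 0.1
    a = (a + a.T) / 2
    b = rng.random((6, 6)) + 0.1
    b = (b + b.T) / 2
    res = compare_maps(ContactMap(a, 1000), ContactMap(b, 1000))
    # direct formula: mean over separations of Pearson of log values
    rs = []
    for s in range(1, 5):
        x = np.log(np.array([a[i, i + s] for i in range(6 - s)]) + 1e-6)
        y = np.log(np.array([b[i, i + s] for i in range(6 - s)]) + 1e-6)
        if len(x) >= 3:
            rs.append(np.corrcoef(x, y)[0, 1])
    assert res["stratified_pearson"] == pytest.approx(np.mean(rs))


def test_compare_maps_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        compare_maps(ContactMap(np.ones((4, 4)), 1000), ContactMap(np.ones((5, 5)), 1000))


def test_directionality_index_sign_convention():
    # bin 2 interacts mostly downstream -> positive DI
    m = np.zeros((7, 7))
    m[2, 4] = m[4, 2] = 5.0
    m[2, 1] = m[1, 2] = 1.0
    di = directionality_index(m, 3)
    assert di[2] > 0


# ---------------------------------------------------------------------------
# geometry


def test_rg_single_bead_is_zero():
    assert radius_of_gyration(np.zeros((1, 3))) == 0.0


def test_rg_square_closed_form():
    P = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
    assert radius_of_gyration(P) == pytest.approx(np.sqrt(0.5))


def test_rg_matches_pair_distance_formula(rng):
    P = rng.normal(size=(30, 3)) * 3
    assert radius_of_gyration(P) == pytest.approx(rg_bruteforce(P), abs=1e-12)


def test_rg_interval_selects_beads():
    P = make_reference_conformation("line", 10)
    assert radius_of_gyration(P, (0, 1000), bead_size=1000) == 0.0
    with pytest.raises(ValueError):
        radius_of_gyration(P, (50_000, 60_000), bead_size=1000)


def test_probe_volume_tetrahedron_closed_form():
    a = 2.0
    P = make_reference_conformation("tetrahedron", 4) * a
    assert probe_volume(P, inflation=0.0) == pytest.approx(a**3 / (6 * np.sqrt(2)))


def test_probe_volume_degenerate_sets_finite_positive():
    line = make_reference_conformation("line", 5)
    v_line = probe_volume(line, inflation=0.5)
    assert v_line == pytest.approx(np.pi * 0.25 * 4 + 4 / 3 * np.pi * 0.125)
    square = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    assert probe_volume(square, inflation=0.5) > 0
    point = np.zeros((1, 3))
    assert probe_volume(point, inflation=0.5) == pytest.approx(4 / 3 * np.pi * 0.125)


def test_probe_volume_matches_bruteforce(rng):
    P = rng.normal(size=(25, 3)) * 2
    assert probe_volume(P, inflation=0.5) == pytest.approx(
        probe_volume_bruteforce(P, 0.5), rel=1e-9)


def test_sigma_conversion_reproduces_printed_constant():
    # sigma ~= 21.8 nm  ->  sigma^3 ~= 1.04e-5 um^3 (3 significant figures)
    assert sigma_cubed_um3() == pytest.approx(1.04e-5, rel=5e-3)


# ---------------------------------------------------------------------------
# expression proxies


def bound_toy(rng, on=True):
    bead_pos = rng.normal(scale=5, size=(10, 1, 20, 3))
    ppos = np.repeat(bead_pos[:, 0, 5:6, :], 2, axis=1)  # proteins glued to bead 5
    ppos = ppos + rng.normal(scale=0.1, size=ppos.shape)
    species = np.array([0, 1], np.int8)
    onarr = np.full((10, 2), on)
    return ensemble_from_positions(bead_pos, None, ppos, species, onarr)


def test_bound_fraction_trivial_cases(rng):
    ens = bound_toy(rng)
    assert bound_fraction(ens, (5000, 6000), 2.0) == 1.0
    ens_off = bound_toy(rng, on=False)
    assert bound_fraction(ens_off, (5000, 6000), 2.0) == 0.0
    no_active = ensemble_from_positions(
        rng.normal(size=(3, 1, 10, 3)), None,
        rng.normal(size=(3, 1, 3)), np.array([1], np.int8), np.ones((3, 1), bool))
    assert bound_fraction(no_active, (0, 1000), 2.0) == 0.0


def test_bound_fraction_requires_protein_records(rng):
    ens = random_ensemble(rng, n_beads=10)
    with pytest.raises(ValueError, match="protein"):
        bound_fraction(ens, (0, 1000))


def test_bound_fraction_matches_hand_count(rng):
    ens = random_ensemble(rng, n_beads=15, n_snapshots=10, n_proteins=4, spread=3.0)
    got = bound_fraction(ens, (4000, 7000), 3.0)
    assert got == pytest.approx(bound_fraction_bruteforce(ens, (4000, 7000), 3.0), abs=1e-12)


def test_enhancer_contact_trivial_and_errors(rng):
    P = np.zeros((1, 1, 10, 3))
    P[0, 0, :, 0] = np.arange(10) * 10.0  # beads far apart
    ens = ensemble_from_positions(P)
    assert enhancer_contact_fraction(ens, (0, 1000), np.array([8, 9]), 3.5) == 0.0
    with pytest.raises(ValueError, match="empty"):
        enhancer_contact_fraction(ens, (0, 1000), np.array([], int), 3.5)
    with pytest.raises(ValueError, match="empty"):
        # promoter's own beads are excluded from the enhancer set
        enhancer_contact_fraction(ens, (0, 2000), np.array([0, 1]), 3.5)


def test_enhancer_contact_monotone_in_cutoff(rng):
    ens = random_ensemble(rng, n_beads=30, n_snapshots=8, spread=4.0)
    enh = np.arange(20, 28)
    prev = 1.1
    for cutoff in (6.0, 4.0, 2.5, 1.0):
        f = enhancer_contact_fraction(ens, (0, 3000), enh, cutoff)
        assert f <= prev + 1e-12
        prev = f


def test_fold_change_of_identical_ensembles_is_one(rng):
    ens = random_ensemble(rng, n_beads=30, n_snapshots=8, spread=3.0)
    enh = np.arange(20, 25)
    f1 = enhancer_contact_fraction(ens, (0, 3000), enh, 4.0)
    f2 = enhancer_contact_fraction(ens, (0, 3000), enh, 4.0)
    assert f1 > 0
    assert f1 / f2 == 1.0
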