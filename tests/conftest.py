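import numpy as np
import pytest

from chromoloop.annotate import BeadAnnotation
from chromoloop.engine import Ensemble


def blank_annotation(n, open_fiber=False, bead_size=1000):
    """Uniform annotation with no binder sites or anchors."""
    z = np.zeros(n, bool)
    return BeadAnnotation(
        active_site=z.copy(),
        het_site=z.copy(),
        pcg_site=z.copy(),
        open_fiber=np.full(n, open_fiber, bool),
        ctcf=np.zeros(n, np.int8),
        ctcf_occupancy=np.zeros(n),
        state_label=[""] * n,
        bead_size=bead_size,
    )


def ensemble_from_positions(bead_pos, annotation=None, protein_pos=None,
                            protein_species=None, protein_on=None, box=50.0):
    """Wrap raw coordinates into an Ensemble for observable tests.

    bead_pos: (S, C, N, 3) or (N, 3) for a single conformation.
    """
    bead_pos = np.asarray(bead_pos, float)
    if bead_pos.ndim == 2:
        bead_pos = bead_pos[None, None]
    S, C, N, _ = bead_pos.shape
    if annotation is None:
        annotation = blank_annotation(N)
    if protein_pos is None:
        protein_pos = np.zeros((S, 0, 3))
        protein_species = np.zeros(0, np.int8)
        protein_on = np.zeros((S, 0), bool)
    return Ensemble(
        bead_pos=bead_pos,
        protein_pos=np.asarray(protein_pos, float),
        protein_species=np.asarray(protein_species, np.int8),
        protein_on=np.asarray(protein_on, bool),
        extruders=np.full((S, 0, 3), -1, dtype=np.int64),
        annotation=annotation,
        box=box,
    )


def random_ensemble(rng, n_beads=30, n_snapshots=5, n_copies=1, n_proteins=0, spread=6.0):
    """Random-coordinate ensemble for brute-force oracle comparisons."""
    bead_pos = rng.normal(scale=spread, size=(n_snapshots, n_copies, n_beads, 3))
    ann = blank_annotation(n_beads)
    if n_proteins:
        ppos = rng.normal(scale=spread, size=(n_snapshots, n_proteins, 3))
        species = rng.integers(0, 3, n_proteins).astype(np.int8)
        on = rng.random((n_snapshots, n_proteins)) < 0.8
        return ensemble_from_positions(bead_pos, ann, ppos, species, on)
    return ensemble_from_positions(bead_pos, ann)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
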