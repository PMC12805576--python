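import numpy as np
import pytest

from mucincg.core import (
    Bead,
    BeadType,
    CGTopology,
    HarmonicBondTerm,
    PeriodicDihedralTerm,
    ReBAngleTerm,
)


@pytest.fixture(scope="session")
def mapping_spec():
    from mucincg.tables import default_mapping_spec

    return default_mapping_spec()


@pytest.fixture(scope="session")
def toy_glycopeptide():
    """5-residue peptide with one Thr-linked sialylated 3-sugar glycan."""
    from mucincg.fixtures import generate_toy_glycopeptide

    return generate_toy_glycopeptide(5, [(1, "SIALYL_T")], seed=1)


@pytest.fixture(scope="session")
def mini2():
    from mucincg.fixtures import build_mini2_construct

    return build_mini2_construct()


def make_chain(
    bonds=((0.35, 5000.0), (0.47, 3000.0), (0.40, 8000.0)),
    angles=((120.0, 50.0), (100.0, 30.0)),
    dihedrals=((3.0, 1, 0.0),),
) -> CGTopology:
    """Linear 4-bead chain with prescribed bonded parameters."""
    bt = BeadType("P2", "R")
    n = len(bonds) + 1
    beads = [
        Bead(i, bt, np.array([0.35 * i, 0.02 * (i % 2), 0.0]),
             [f"{i}:X1", f"{i}:X2"])
        for i in range(n)
    ]
    return CGTopology(
        beads=beads,
        bonds=[HarmonicBondTerm(i, i + 1, r0, k)
               for i, (r0, k) in enumerate(bonds)],
        angles=[ReBAngleTerm(i, i + 1, i + 2, t0, k)
                for i, (t0, k) in enumerate(angles)],
        dihedrals=[PeriodicDihedralTerm(i, i + 1, i + 2, i + 3, k, mult, ps)
                   for i, (k, mult, ps) in enumerate(dihedrals)],
        n_term=0,
        c_term=n - 1,
    )


def random_bead_assembly(rng: np.random.Generator, n_beads: int) -> CGTopology:
    """Loose cluster of beads with mixed size classes (for SASA/volume oracles)."""
    classes = ["T", "S", "R"]
    beads = []
    for i in range(n_beads):
        cls = classes[int(rng.integers(3))]
        beads.append(Bead(
            i, BeadType(f"X{cls}", cls), rng.uniform(0, 0.8, 3),
            [f"{i}:A", f"{i}:B"]))
    return CGTopology(beads=beads)
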