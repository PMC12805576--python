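"""Atomistic-to-CG mapping: placement, partition, O-glycan conventions."""

from dataclasses import replace

import numpy as np
import pytest

from mucincg.core import BeadType, net_charge
from mucincg.mapper import (
    Atom,
    AtomisticStructure,
    BeadTemplate,
    ConsistencyError,
    MappingError,
    MappingSpec,
    ResidueTemplate,
    TrajectoryFrameSet,
    UnmappedResidueError,
    UnsupportedAttachmentError,
    UnsupportedRingError,
    add_ring_virtual_sites,
    apply_glycosidic_linkage,
    apply_protein_glycan_attachment,
    map_structure,
    map_trajectory,
)


def one_bead_spec():
    """Three-atom single-bead residue template ('X')."""
    tpl = ResidueTemplate(
        resname="X",
        beads=(BeadTemplate("BD", "SX", ("A1", "A2", "A3")),),
        intra_bonds=(),
    )
    return MappingSpec(templates={"X": tpl},
                       bead_types={"SX": BeadType("SX", "S")})


def three_residue_structure():
    atoms, bonds = [], []
    for r in range(3):
        base = np.array([1.0 * r, 0.0, 0.0])
        for k, (name, off) in enumerate(zip(
                ("A1", "A2", "A3"),
                ([0.07, 0, 0], [-0.035, 0.06, 0], [-0.035, -0.06, 0]))):
            atoms.append(Atom(name, name[0], r + 1, "X", base + np.array(off)))
            if k:
                bonds.append((len(atoms) - 2, len(atoms) - 1))
        if r:
            bonds.append((len(atoms) - 4, len(atoms) - 3))  # inter-residue
    return AtomisticStructure(atoms=atoms, bonds=bonds)


class TestMapStructure:
    def test_center_of_geometry_placement(self):
        spec = one_bead_spec()
        atoms = [Atom("A1", "A", 1, "X", np.array([0.0, 0, 0])),
                 Atom("A2", "A", 1, "X", np.array([1.0, 0, 0])),
                 Atom("A3", "A", 1, "X", np.array([0.5, 0, 0]))]
        topo = map_structure(AtomisticStructure(atoms=atoms, bonds=[]), spec)
        assert np.allclose(topo.beads[0].position, [0.5, 0, 0])

    def test_three_residue_enumeration(self):
        # 9 pseudo-atoms, 3 one-bead templates -> 3 beads, 2 bonds, 1 angle
        topo = map_structure(three_residue_structure(), one_bead_spec())
        assert len(topo.beads) == 3
        assert len(topo.bonds) == 2
        assert len(topo.angles) == 1
        assert len(topo.dihedrals) == 0

    def test_unmapped_residue_error(self):
        s = three_residue_structure()
        bad = AtomisticStructure(
            atoms=[replace(a, residue_name="ZZZ") for a in s.atoms],
            bonds=s.bonds)
        with pytest.raises(UnmappedResidueError):
            map_structure(bad, one_bead_spec())

    def test_missing_named_atom_reported(self):
        s = three_residue_structure()
        bad = AtomisticStructure(atoms=s.atoms[1:], bonds=None)
        with pytest.raises(MappingError, match="A1"):
            map_structure(bad, one_bead_spec())

    def test_partition_property_on_fixture(self, toy_glycopeptide):
        structure, spec, topo = toy_glycopeptide
        n_heavy = len(structure.heavy_indices())
        assert sum(len(b.constituent_atoms) for b in topo.beads) == n_heavy

    def test_equivariance_under_rigid_motion(self, toy_glycopeptide):
        structure, spec, _ = toy_glycopeptide
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        shift = np.array([1.0, -2.0, 3.0])
        moved = AtomisticStructure(
            atoms=[replace(a, position=a.position @ rot.T + shift)
                   for a in structure.atoms],
            bonds=structure.bonds)
        ref = map_structure(structure, spec).coordinates()
        got = map_structure(moved, spec).coordinates()
        assert np.abs(got - (ref @ rot.T + shift)).max() < 1e-10


class TestGlycosidicConventions:
    def test_donor_anomeric_retyped_tc5(self, toy_glycopeptide):
        # GalNAc donates to the protein: its anomeric bead is a 2-atom TC5
        _, _, topo = toy_glycopeptide
        galnac = [b for b in topo.beads
                  if topo.residue_names[b.residue_id] == "GALNAC"
                  and b.name == "A"]
        assert galnac and all(b.bead_type.name == "TC5" for b in galnac)
        assert all(len(b.constituent_atoms) == 2 for b in galnac)

    def test_unlinked_sugar_keeps_sn6(self, mapping_spec):
        # a free galactose (anomeric hydroxyl present) maps to SN6
        tpl = mapping_spec.templates["GAL"]
        atoms, base = [], np.array([0.0, 0.0, 0.0])
        offs = {"A": [0, 0, 0], "B": [0.3, 0, 0], "C": [0.15, 0.25, 0]}
        for bt in tpl.beads:
            for k, aname in enumerate(bt.atoms):
                atoms.append(Atom(aname, aname[0], 1, "GAL",
                                  base + np.array(offs[bt.name]) +
                                  np.array([0.02 * k, 0.03 * (k % 2), 0.01])))
        topo = map_structure(AtomisticStructure(atoms=atoms, bonds=[]),
                             mapping_spec)
        ano = next(b for b in topo.beads if b.name == "A")
        assert ano.bead_type.name == "SN6"
        assert len(ano.constituent_atoms) == 3

    def test_bridging_oxygen_belongs_to_acceptor(self, toy_glycopeptide):
        _, spec, topo = toy_glycopeptide
        for b in topo.beads:
            resname = topo.residue_names.get(b.residue_id, "")
            tpl = spec.templates.get(resname)
            if tpl is None or tpl.category != "sugar" or tpl.acceptor_atom is None:
                continue
            bridge = f"{b.residue_id}:{tpl.acceptor_atom}"
            owners = [x for x in topo.beads if bridge in x.constituent_atoms]
            if owners:
                assert owners[0].residue_id == b.residue_id

    def test_misassigned_bridging_oxygen_raises(self, toy_glycopeptide):
        # GAL (donor) -> GALNAC (acceptor): move O3 into a donor bead
        _, spec, topo = toy_glycopeptide
        galnac_rid = next(r for r, n in topo.residue_names.items() if n == "GALNAC")
        gal_rid = next(r for r, n in topo.residue_names.items() if n == "GAL")
        bridge = f"{galnac_rid}:O3"
        bad = topo.copy()
        owner = next(x for x in bad.beads if bridge in x.constituent_atoms)
        donor_bead = next(x for x in bad.beads
                          if x.residue_id == gal_rid and x.name == "B")
        owner.constituent_atoms.remove(bridge)
        donor_bead.constituent_atoms.append(bridge)
        with pytest.raises(ConsistencyError):
            apply_glycosidic_linkage(bad, gal_rid, galnac_rid, spec)


class TestProteinAttachment:
    def test_thr_linkage_sn4ar(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        site = topo.attachment_residues[min(topo.attachment_residues)]
        link = next(b for b in topo.beads
                    if b.residue_id == site and b.name == "SC1")
        assert link.bead_type.name == "SN4ar"

    def test_ser_linkage_tn4ar(self):
        from mucincg.fixtures import generate_toy_glycopeptide

        _, _, topo = generate_toy_glycopeptide(4, [(2, "TN")], seed=3)
        link = next(b for b in topo.beads
                    if b.residue_id == 2 and b.name == "SC1")
        assert link.bead_type.name == "TN4ar"

    def test_sulfated_sugar_carries_q4n(self):
        from mucincg.fixtures import generate_toy_glycopeptide

        _, _, topo = generate_toy_glycopeptide(4, [(1, "SULFO_T")], seed=3)
        q4n = [b for b in topo.beads if b.bead_type.name == "Q4n"]
        assert len(q4n) == 1 and q4n[0].charge == -1
        assert net_charge(topo) == -1

    def test_attachment_to_proline_rejected(self, toy_glycopeptide, mapping_spec):
        _, _, topo = toy_glycopeptide
        pro = next(r for r, n in topo.residue_names.items() if n == "PRO")
        glycan = min(topo.attachment_residues)
        with pytest.raises(UnsupportedAttachmentError):
            apply_protein_glycan_attachment(topo, pro, glycan, mapping_spec)


class TestRingVirtualSites:
    def test_centroid_placement(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        for gid, members in topo.rigid_groups.items():
            vs = [topo.beads_by_id[m] for m in members
                  if topo.beads_by_id[m].is_virtual]
            real = [topo.beads_by_id[m] for m in members
                    if not topo.beads_by_id[m].is_virtual]
            assert len(vs) == 1 and len(real) == 3
            centroid = np.mean([b.position for b in real], axis=0)
            assert np.allclose(vs[0].position, centroid)
            assert vs[0].bead_type.name == "TC4"
            assert vs[0].mass < 1e-6

    def test_one_site_per_ring(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        n_rings = len(topo.rigid_groups)
        assert sum(b.is_virtual for b in topo.beads) == n_rings == 3

    def test_idempotence(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        again = add_ring_virtual_sites(topo)
        assert len(again.beads) == len(topo.beads)

    def test_degenerate_ring_rejected(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        broken = topo.copy()
        gid = min(broken.rigid_groups)
        members = sorted(m for m in broken.rigid_groups[gid]
                         if not broken.beads_by_id[m].is_virtual)
        broken.rigid_groups[gid] = set(members[:2])
        with pytest.raises(UnsupportedRingError):
            add_ring_virtual_sites(broken)


class TestMapTrajectory:
    def test_single_frame_matches_map_structure(self, toy_glycopeptide,
                                                mapping_spec):
        structure, spec, _ = toy_glycopeptide
        frames = TrajectoryFrameSet(structure.positions()[None])
        cg = map_trajectory(frames, structure, spec)
        ref = map_structure(structure, spec)
        assert np.allclose(cg.positions[0], ref.coordinates())

    def test_translation_equivariance(self, toy_glycopeptide):
        structure, spec, _ = toy_glycopeptide
        p = structure.positions()
        frames = TrajectoryFrameSet(np.stack([p, p + 1.0]))
        cg = map_trajectory(frames, structure, spec)
        assert np.allclose(cg.positions[1] - cg.positions[0], 1.0)

    def test_shape_contract(self, toy_glycopeptide):
        structure, spec, _ = toy_glycopeptide
        p = structure.positions()
        frames = TrajectoryFrameSet(np.stack([p] * 100))
        cg = map_trajectory(frames, structure, spec)
        assert cg.n_frames == 100
        assert cg.n_sites == len(map_structure(structure, spec).beads)

    def test_atom_count_mismatch_rejected(self, toy_glycopeptide):
        structure, spec, _ = toy_glycopeptide
        frames = TrajectoryFrameSet(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="atoms"):
            map_trajectory(frames, structure, spec)
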