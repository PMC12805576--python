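"""System assembly: solvation arithmetic, volume, packing, file export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mucincg.builder as B
from mucincg.builder import (
    BoxSpec,
    GeometryError,
    PackingError,
    SolvationPlan,
    build_repeats,
    estimate_molecular_volume,
    ion_pairs,
    pack_system,
    plan_solvation,
    read_gromacs,
    read_lammps_data,
    write_gromacs,
    write_lammps_data,
)
from mucincg.core import Bead, BeadType, CGTopology, net_charge

from conftest import make_chain, random_bead_assembly


class TestSolvationArithmetic:
    def test_published_ion_pairs(self):
        # 15,860 W beads at 150 mM on the represented water volume
        assert ion_pairs(15860, 0.150) == 171

    def test_published_full_composition(self):
        # choose the solute volume so the 12.5 nm box holds exactly 15,860 W
        v = 12.5**3 - (15860 + 0.5) * B.WATERS_PER_BEAD / B.WATER_NUMBER_DENSITY
        plan = plan_solvation(BoxSpec(12.5), v, -13, 0.150)
        assert plan.n_water_beads == 15860
        assert plan.n_na == 184          # 171 background + 13 neutralizing
        assert plan.n_cl == 171

    def test_neutral_zero_concentration(self):
        plan = plan_solvation(BoxSpec(5.0), 1.0, 0, 0.0)
        assert plan.n_na == 0 and plan.n_cl == 0

    def test_cationic_solute_gets_anions(self):
        plan = plan_solvation(BoxSpec(5.0), 1.0, +5, 0.0)
        assert plan.n_na == 0 and plan.n_cl == 5

    def test_four_waters_per_bead(self):
        # water-bead count is exactly (free volume * molecular density) / 4
        box, vsol = BoxSpec(6.0), 10.0
        plan = plan_solvation(box, vsol, 0, 0.0)
        n_molecules = (box.volume - vsol) * B.WATER_NUMBER_DENSITY
        assert plan.n_water_beads == int(n_molecules // 4)
        assert B.WATERS_PER_BEAD == 4

    def test_oversized_solute_rejected(self):
        with pytest.raises(GeometryError):
            plan_solvation(BoxSpec(2.0), 10.0, 0, 0.15)

    @given(st.integers(-20, 20), st.floats(0.0, 0.5), st.floats(2.0, 20.0))
    @settings(max_examples=50, derandomize=True)
    def test_electroneutrality(self, charge, conc, edge):
        plan = plan_solvation(BoxSpec(edge), 0.1 * edge**3, charge, conc)
        assert charge + plan.n_na - plan.n_cl == 0

    def test_monotonicity(self):
        box = BoxSpec(8.0)
        waters = [plan_solvation(box, v, 0, 0.15).n_water_beads
                  for v in (5.0, 20.0, 100.0)]
        assert waters == sorted(waters, reverse=True)
        pairs = [ion_pairs(10_000, c) for c in (0.0, 0.05, 0.15, 0.5)]
        assert pairs == sorted(pairs)


class TestMolecularVolume:
    def _single(self, cls="R"):
        return CGTopology(beads=[Bead(0, BeadType("X", cls), np.zeros(3),
                                      ["1:A", "1:B"])])

    def test_single_sphere(self):
        v = estimate_molecular_volume(self._single())
        exact = 4.0 / 3.0 * np.pi * 0.264**3
        assert abs(v - exact) / exact < 0.02

    def test_far_separated_additivity(self):
        bt = BeadType("X", "R")
        topo = CGTopology(beads=[
            Bead(0, bt, np.zeros(3), ["1:A", "1:B"]),
            Bead(1, bt, np.array([5.0, 0, 0]), ["2:A", "2:B"])])
        v1 = estimate_molecular_volume(self._single())
        assert abs(estimate_molecular_volume(topo) - 2 * v1) / (2 * v1) < 0.02

    def test_coincident_union_semantics(self):
        bt = BeadType("X", "R")
        topo = CGTopology(beads=[
            Bead(0, bt, np.zeros(3), ["1:A", "1:B"]),
            Bead(1, bt, np.zeros(3), ["2:A", "2:B"])])
        v1 = estimate_molecular_volume(self._single())
        assert abs(estimate_molecular_volume(topo) - v1) / v1 < 0.02

    def test_empty_topology(self):
        assert estimate_molecular_volume(CGTopology(beads=[])) == 0.0

    def test_against_hit_or_miss_oracle(self):
        """Grid union volume vs independent Monte-Carlo integration."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            topo = random_bead_assembly(rng, 5)
            coords = topo.coordinates()
            radii = np.array([b.bead_type.vdw_radius for b in topo.beads])
            lo = (coords - radii[:, None]).min(axis=0)
            hi = (coords + radii[:, None]).max(axis=0)
            pts = rng.uniform(lo, hi, (1_000_000, 3))
            inside = np.zeros(len(pts), dtype=bool)
            for c, r in zip(coords, radii):
                inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
            mc = inside.mean() * np.prod(hi - lo)
            grid = estimate_molecular_volume(topo)
            assert abs(grid - mc) / mc < 0.01


class TestPacking:
    def test_no_insertions_leaves_solute_unchanged(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        plan = SolvationPlan(0, 0, 0, 0.0, 1.0, 0)
        packed = pack_system(topo, plan, BoxSpec(10.0), seed=1)
        assert np.array_equal(packed.solute_coords, topo.coordinates())
        assert len(packed.water_coords) == 0

    def test_min_distance_enforced(self, toy_glycopeptide):
        from scipy.spatial.distance import cdist, pdist

        _, _, topo = toy_glycopeptide
        plan = SolvationPlan(100, 0, 0, 0.0, 1.0, 0)
        packed = pack_system(topo, plan, BoxSpec(10.0), min_dist=0.4, seed=7)
        w = packed.water_coords
        assert len(w) == 100
        assert pdist(w).min() >= 0.4
        solute = np.array([b.position for b in topo.beads if not b.is_virtual])
        assert cdist(w, np.mod(solute, 10.0)).min() >= 0.4

    def test_determinism(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        plan = SolvationPlan(50, 2, 2, 0.15, 1.0, 0)
        a = pack_system(topo, plan, BoxSpec(8.0), seed=3)
        b = pack_system(topo, plan, BoxSpec(8.0), seed=3)
        assert np.array_equal(a.all_coordinates(), b.all_coordinates())

    def test_infeasible_density_fails_with_diagnostic(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        plan = SolvationPlan(1_000_000, 0, 0, 0.0, 1.0, 0)
        with pytest.raises(PackingError, match="density"):
            pack_system(topo, plan, BoxSpec(2.0), max_attempts=200, seed=0)


class TestWriters:
    def test_gromacs_round_trip_byte_stable(self, toy_glycopeptide, tmp_path):
        _, _, topo = toy_glycopeptide
        coords = topo.coordinates()
        write_gromacs(topo, coords, tmp_path / "a", box_edge=8.0)
        t2, c2, box = read_gromacs(tmp_path / "a")
        write_gromacs(t2, c2, tmp_path / "b", box_edge=box)
        assert (tmp_path / "a.itp").read_text() == (tmp_path / "b.itp").read_text()
        a_gro = (tmp_path / "a.gro").read_text().split("\n", 1)[1]
        b_gro = (tmp_path / "b.gro").read_text().split("\n", 1)[1]
        assert a_gro == b_gro

    def test_gromacs_round_trip_preserves_terms(self, toy_glycopeptide, tmp_path):
        _, _, topo = toy_glycopeptide
        write_gromacs(topo, topo.coordinates(), tmp_path / "a", box_edge=8.0)
        t2, _, _ = read_gromacs(tmp_path / "a")
        assert len(t2.beads) == len(topo.beads)
        assert [b.bead_type.name for b in t2.beads] == \
            [b.bead_type.name for b in topo.beads]
        assert len(t2.bonds) == len(topo.bonds)
        assert len(t2.angles) == len(topo.angles)
        assert len(t2.dihedrals) == len(topo.dihedrals)
        assert sum(b.is_virtual for b in t2.beads) == \
            sum(b.is_virtual for b in topo.beads)
        got = sorted((t.i, t.j, round(t.r0, 5)) for t in t2.bonds)
        want = sorted((t.i, t.j, round(t.r0, 5)) for t in topo.bonds)
        assert got == want

    def test_lammps_round_trip_byte_stable(self, toy_glycopeptide, tmp_path):
        _, _, topo = toy_glycopeptide
        (tmp_path / "d2").mkdir()
        write_lammps_data(topo, topo.coordinates(), tmp_path / "a.data",
                          box_edge=8.0)
        t2, c2, box = read_lammps_data(tmp_path / "a.data")
        write_lammps_data(t2, c2, tmp_path / "d2" / "a.data", box_edge=box)
        a = (tmp_path / "a.data").read_text()
        b = (tmp_path / "d2" / "a.data").read_text()
        assert a == b
        assert (tmp_path / "a.table").read_text() == \
            (tmp_path / "d2" / "a.table").read_text()

    def test_lammps_bond_constant_dialect(self, tmp_path):
        # internal 1/2 k convention, k_b = 5000 kJ/mol/nm^2
        #   -> LAMMPS V = K x^2 with K = 2500 kJ/mol/nm^2 = 5.9751 kcal/mol/A^2
        topo = make_chain(bonds=((0.35, 5000.0),), angles=(), dihedrals=())
        write_lammps_data(topo, topo.coordinates(), tmp_path / "k.data",
                          box_edge=5.0)
        line = next(l for l in (tmp_path / "k.data").read_text().splitlines()
                    if l.strip().startswith("1 ") and "k_b=" in l)
        K = float(line.split()[1])
        assert K == pytest.approx(5000.0 / 2 / 4.184 / 100.0, abs=1e-6)
        assert K == pytest.approx(5.9751, abs=1e-4)

    def test_unit_contract_nm_vs_angstrom(self, tmp_path):
        topo = make_chain(bonds=((0.35, 5000.0),), angles=(), dihedrals=())
        coords = topo.coordinates()
        write_gromacs(topo, coords, tmp_path / "u", box_edge=5.0)
        write_lammps_data(topo, coords, tmp_path / "u.data", box_edge=5.0)
        _, c_gro, _ = read_gromacs(tmp_path / "u")
        _, c_lmp, _ = read_lammps_data(tmp_path / "u.data")
        assert np.allclose(c_gro, coords, atol=1e-3)       # written in nm
        assert np.allclose(c_lmp, coords, atol=1e-7)       # A / 10
        raw = (tmp_path / "u.data").read_text()
        assert "3.500000" in raw                           # 0.35 nm -> 3.5 A

    def test_lammps_angle_table_format(self, toy_glycopeptide, tmp_path):
        _, _, topo = toy_glycopeptide
        write_lammps_data(topo, topo.coordinates(), tmp_path / "t.data",
                          box_edge=8.0)
        table = (tmp_path / "t.table").read_text()
        assert "N 721" in table
        first = next(l for l in table.splitlines()
                     if l and l[0].isdigit() and len(l.split()) == 4)
        assert first.split()[0] == "1"


class TestBuildRepeats:
    def test_identity_for_single_repeat(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        rep = build_repeats(topo, 1)
        assert len(rep.beads) == len(topo.beads)
        assert rep.total_mass() == pytest.approx(topo.total_mass())
        assert net_charge(rep) == net_charge(topo)

    def test_charge_and_mass_additivity(self, toy_glycopeptide):
        _, _, topo = toy_glycopeptide
        rep = build_repeats(topo, 3)
        assert net_charge(rep) == 3 * net_charge(topo)
        assert rep.total_mass() == pytest.approx(3 * topo.total_mass())
        assert len(rep.bonds) == 3 * len(topo.bonds) + 2   # two junctions

    def test_five_repeats_of_mini2_give_150_residues(self, mini2):
        rep = build_repeats(mini2, 5)
        assert rep.n_residues == 150
        assert rep.n_glycans() == 5 * 18
        assert net_charge(rep) == -65

    def test_invalid_count_rejected(self, mini2):
        with pytest.raises(ValueError):
            build_repeats(mini2, 0)

    def test_junction_connects_termini(self):
        chain = make_chain()
        rep = build_repeats(chain, 2)
        junction = rep.bonds[-1]
        assert {junction.i, junction.j} == {chain.c_term, chain.n_term + 4}
        # copies do not overlap
        c = rep.coordinates()
        assert np.linalg.norm(c[4] - c[3]) > 0.3
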