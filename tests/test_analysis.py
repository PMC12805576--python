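"""Structural metrics: Rg, Ree, SASA, RDF, RMSD, Flory fit, LJ downscaling."""

import numpy as np
import pytest

from mucincg.analysis import (
    SasaConfig,
    SelectionError,
    downscale_protein_lj,
    end_to_end_distance,
    fit_flory,
    radius_of_gyration,
    rdf,
    rmsd_pseudo_cg,
    sasa,
)
from mucincg.core import Bead, BeadType, CGTopology
from mucincg.mapper import TrajectoryFrameSet
from mucincg.tables import load_lj_table

from conftest import random_bead_assembly


def rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestRadiusOfGyration:
    def test_single_particle(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.ones(1)) == 0.0

    def test_two_unit_masses(self):
        p = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(p, np.ones(2)) == pytest.approx(0.5)

    def test_square_configuration(self):
        p = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0],
                      [-0.5, -0.5, 0]])
        assert radius_of_gyration(p, np.ones(4)) == pytest.approx(np.sqrt(0.5))

    def test_virtual_masses_excluded(self):
        p = np.array([[0.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        m = np.array([1.0, 1.0, 1e-10])
        assert radius_of_gyration(p, m) == pytest.approx(0.5)

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            radius_of_gyration(np.zeros((2, 3)), np.full(2, 1e-10))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(20, 3))
        m = rng.uniform(30, 80, 20)
        assert radius_of_gyration(p + 7.0, m) == pytest.approx(
            radius_of_gyration(p, m))


class TestEndToEnd:
    def test_coincident(self):
        assert end_to_end_distance(np.zeros(3), np.zeros(3)) == 0.0

    def test_straight_chain(self):
        assert end_to_end_distance(np.zeros(3),
                                   np.array([3.5, 0, 0])) == pytest.approx(3.5)

    def test_pythagorean(self):
        assert end_to_end_distance(np.zeros(3),
                                   np.array([1.0, 2.0, 2.0])) == pytest.approx(3.0)


class TestSasa:
    def _single(self, cls="R"):
        return CGTopology(beads=[Bead(0, BeadType("X", cls), np.zeros(3),
                                      ["1:A", "1:B"])])

    def test_single_sphere_analytic(self):
        topo = self._single()
        total, per = sasa(topo, topo.coordinates())
        exact = 4 * np.pi * (0.264 + 0.191) ** 2
        assert abs(total - exact) / exact < 0.01

    def test_distant_beads_additive(self):
        bt = BeadType("X", "R")
        topo = CGTopology(beads=[Bead(0, bt, np.zeros(3), ["1:A", "1:B"]),
                                 Bead(1, bt, np.array([3.0, 0, 0]),
                                      ["2:A", "2:B"])])
        total, _ = sasa(topo, topo.coordinates())
        exact = 2 * 4 * np.pi * (0.264 + 0.191) ** 2
        assert abs(total - exact) / exact < 0.01

    def test_buried_bead_has_zero_area(self):
        # a tiny bead fully enclosed by a tight shell of regular beads
        beads = [Bead(0, BeadType("X", "T"), np.zeros(3), ["0:A", "0:B"])]
        k = 1
        for x in (-0.3, 0.3):
            for y in (-0.3, 0.3):
                for z in (-0.3, 0.3):
                    beads.append(Bead(k, BeadType("Y", "R"),
                                      np.array([x, y, z]), [f"{k}:A", f"{k}:B"]))
                    k += 1
        topo = CGTopology(beads=beads)
        _, per = sasa(topo, topo.coordinates())
        assert per[0] == 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        topo = random_bead_assembly(rng, 6)
        coords = topo.coordinates()
        t0, _ = sasa(topo, coords)
        moved = coords @ rotation(1.1).T + np.array([3.0, -1.0, 2.0])
        t1, _ = sasa(topo, moved)
        assert abs(t1 - t0) / t0 < 0.005

    def test_negative_probe_rejected(self):
        with pytest.raises(ValueError):
            SasaConfig(probe_radius=-0.1)

    def test_against_hit_or_miss_oracle(self):
        """Sphere-point SASA vs independent random-point surface integration."""
        rng = np.random.default_rng(31)
        cfg = SasaConfig()
        for _ in range(20):
            topo = random_bead_assembly(rng, 6)
            coords = topo.coordinates()
            radii = np.array([cfg.radii[b.bead_type.size_class]
                              for b in topo.beads]) + cfg.probe_radius
            total_mc = 0.0
            for i in range(len(coords)):
                n = 20_000
                v = rng.normal(size=(n, 3))
                v /= np.linalg.norm(v, axis=1)[:, None]
                pts = coords[i] + radii[i] * v
                exposed = np.ones(n, dtype=bool)
                for j in range(len(coords)):
                    if j == i:
                        continue
                    exposed &= np.sum((pts - coords[j]) ** 2, axis=1) > radii[j] ** 2
                total_mc += 4 * np.pi * radii[i] ** 2 * exposed.mean()
            total, _ = sasa(topo, coords, cfg)
            assert abs(total - total_mc) / total_mc < 0.02


class TestRdf:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10.0, (2000, 3))
        prof = rdf(pts, pts, 10.0, bins=25)
        assert np.abs(prof.g[1:] - 1.0).max() < 0.1

    def test_normalization_integral(self):
        rng = np.random.default_rng(2)
        n = 2000
        pts = rng.uniform(0, 10.0, (n, 3))
        prof = rdf(pts, pts, 10.0, bins=25)
        # pairs counted within r_max plus the ideal-gas tail outside the sphere
        within = prof.counts.sum() / n
        v_sphere = 4.0 / 3.0 * np.pi * 5.0**3
        tail = (n - 1) / 1000.0 * (1000.0 - v_sphere)
        assert abs((within + tail) - (n - 1)) / (n - 1) < 0.02

    def test_two_fixed_particles_single_bin(self):
        a = np.array([[1.0, 1.0, 1.0]])
        b = np.array([[1.0, 1.0, 3.0]])
        prof = rdf(a, b, 20.0, bins=100, r_max=10.0)
        nonzero = np.nonzero(prof.counts)[0]
        assert len(nonzero) == 1
        assert abs(prof.bin_centers[nonzero[0]] - 2.0) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(SelectionError):
            rdf(np.empty((0, 3)), np.ones((5, 3)), 10.0)

    def test_r_max_bounded_by_half_box(self):
        pts = np.random.default_rng(3).uniform(0, 5, (50, 3))
        with pytest.raises(ValueError):
            rdf(pts, pts, 5.0, r_max=4.0)


class TestRmsd:
    def test_identical_frame(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3))
        traj = TrajectoryFrameSet(ref[None])
        assert rmsd_pseudo_cg(traj, ref)[0] == pytest.approx(0.0, abs=1e-12)

    def test_superposition_removes_rigid_rotation(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(12, 3))
        moved = ref @ rotation(0.8).T + 4.0
        traj = TrajectoryFrameSet(moved[None])
        assert rmsd_pseudo_cg(traj, ref, superpose=True)[0] < 1e-8

    def test_single_displaced_bead_without_superposition(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(10, 3))
        moved = ref.copy()
        moved[0] += np.array([0.1, 0.0, 0.0])
        traj = TrajectoryFrameSet(moved[None])
        got = rmsd_pseudo_cg(traj, ref, superpose=False)[0]
        assert got == pytest.approx(np.sqrt(0.01 / 10), rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd_pseudo_cg(TrajectoryFrameSet(np.zeros((1, 5, 3))),
                           np.zeros((6, 3)))


class TestFloryFit:
    def test_exact_recovery_on_power_law(self):
        mw = np.array([1e3, 5e3, 2e4, 1e5, 5e5, 2e6])
        rg = 1.0 * mw**0.6
        fit = fit_flory(rg, mw)
        assert fit.v == pytest.approx(0.6, abs=1e-12)
        assert fit.R0 == pytest.approx(1.0, rel=1e-10)

    def test_two_point_slope(self):
        fit = fit_flory(np.array([1.0, 10**0.5]), np.array([1.0, 10.0]))
        assert fit.v == pytest.approx(0.5)

    def test_unbiased_under_lognormal_noise(self):
        """Mean fitted exponent over 500 noisy replicates is within 0.01."""
        rng = np.random.default_rng(7)
        mw = np.logspace(3, 6, 6)
        v_true = 0.55
        vs = []
        for _ in range(500):
            rg = 2.0 * mw**v_true * np.exp(rng.normal(0.0, 0.05, mw.size))
            vs.append(fit_flory(rg, mw).v)
        assert abs(np.mean(vs) - v_true) < 0.01

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_flory(np.array([1.0, -1.0]), np.array([1.0, 2.0]))


class TestDownscaling:
    def test_protein_protein_scaled(self):
        lj = load_lj_table()
        scaled = downscale_protein_lj(lj, 0.88)
        _, e0 = lj.get("P2", "P2")
        _, e1 = scaled.get("P2", "P2")
        assert e1 == pytest.approx(0.88 * e0)

    def test_protein_water_untouched(self):
        lj = load_lj_table()
        scaled = downscale_protein_lj(lj, 0.88)
        assert scaled.get("P2", "W") == lj.get("P2", "W")
        assert scaled.get("W", "W") == lj.get("W", "W")
        assert scaled.get("TQ5+", "P2") == lj.get("TQ5+", "P2")

    def test_sigma_unchanged(self):
        lj = load_lj_table()
        scaled = downscale_protein_lj(lj, 0.88)
        for (a, b), (sigma, _) in lj.pairs():
            assert scaled.get(a, b)[0] == sigma

    def test_identity_factor(self):
        lj = load_lj_table()
        assert downscale_protein_lj(lj, 1.0) == lj

    def test_factor_composition(self):
        lj = load_lj_table()
        a = downscale_protein_lj(downscale_protein_lj(lj, 0.88), 0.5)
        b = downscale_protein_lj(lj, 0.44)
        for (x, y), (_, eps) in a.pairs():
            assert eps == pytest.approx(b.get(x, y)[1], rel=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            downscale_protein_lj(load_lj_table(), 0.0)
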