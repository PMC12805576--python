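"""Core domain types for coarse-grained (CG) mucin models.

The MARTINI 3 scheme groups 2-4 heavy atoms into one interaction bead.
Beads come in three size classes -- tiny (T, 2 atoms), small (S, 3 atoms)
and regular (R, 4 atoms) -- with van der Waals radii of 0.191, 0.230 and
0.264 nm respectively.  A :class:`CGTopology` collects the beads of one
molecule together with its bonded terms (harmonic bonds, restricted-bending
angles, periodic dihedrals), the rigid monosaccharide ring groups and the
bead connectivity graph.

Internal unit conventions: lengths in nm, energies in kJ/mol, masses in Da,
angles in degrees at API boundaries (converted to radians internally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "SIZE_CLASS_RADII",
    "SIZE_CLASS_MASSES",
    "SIZE_CLASS_ATOMS",
    "VIRTUAL_MASS",
    "InvalidGeometryError",
    "SingularityError",
    "BeadType",
    "Bead",
    "HarmonicBondTerm",
    "ReBAngleTerm",
    "PeriodicDihedralTerm",
    "CGTopology",
    "NonbondedParams",
    "evaluate_bond_energy",
    "evaluate_reb_angle_energy",
    "evaluate_dihedral_energy",
    "net_charge",
]

#: Boltzmann constant in kJ mol^-1 K^-1 (GROMACS convention).
KB = 0.0083145
#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 300.0

#: vdW radius (nm) per bead size class; tiny/small/regular.
SIZE_CLASS_RADII = {"T": 0.191, "S": 0.230, "R": 0.264}
#: Bead mass (Da) per size class, MARTINI 3 convention.
SIZE_CLASS_MASSES = {"T": 36.0, "S": 54.0, "R": 72.0}
#: Number of constituent heavy atoms per size class.
SIZE_CLASS_ATOMS = {"T": 2, "S": 3, "R": 4}
#: Mass (Da) assigned to massless virtual sites (numerically negligible).
VIRTUAL_MASS = 1e-10


class InvalidGeometryError(ValueError):
    """A geometric argument is outside the physical domain of a potential."""


class SingularityError(InvalidGeometryError):
    """Evaluation requested at a singular point of a potential."""


@dataclass(frozen=True)
class BeadType:
    """A CG bead chemotype (e.g. TC5, SN4ar, Q4n, W, TQ5).

    ``vdw_radius`` and ``mass`` default from the size class and may only be
    overridden explicitly (e.g. through a user parameter table).
    """

    name: str
    size_class: str
    charge: int = 0
    vdw_radius: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASS_RADII:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.charge not in (-1, 0, 1):
            raise ValueError(f"bead charge must be -1, 0 or +1, got {self.charge}")
        if self.vdw_radius is None:
            object.__setattr__(self, "vdw_radius", SIZE_CLASS_RADII[self.size_class])
        if self.mass is None:
            object.__setattr__(self, "mass", SIZE_CLASS_MASSES[self.size_class])


@dataclass
class Bead:
    """One CG interaction site of a molecule.

    ``constituent_atoms`` holds atom identifiers ("resid:atomname") of the
    heavy atoms mapped into the bead; it is empty exactly for virtual sites.
    """

    id: int
    bead_type: BeadType
    position: np.ndarray
    constituent_atoms: list[str] = field(default_factory=list)
    is_virtual: bool = False
    rigid_group: int | None = None
    residue_id: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.is_virtual and self.constituent_atoms:
            raise ValueError("virtual beads carry no constituent atoms")

    @property
    def mass(self) -> float:
        return VIRTUAL_MASS if self.is_virtual else float(self.bead_type.mass)

    @property
    def charge(self) -> int:
        return self.bead_type.charge


# ---------------------------------------------------------------------------
# Bonded terms.  Each term evaluates its own energy and analytic gradient
# with respect to its scalar internal coordinate (r, theta or phi).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicBondTerm:
    """Harmonic bond V(r) = 1/2 k_b (r - r0)^2, r0 in nm, k_b in kJ/mol/nm^2."""

    i: int
    j: int
    r0: float
    k_b: float

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.k_b <= 0:
            raise ValueError("k_b must be positive")

    def energy(self, r: float) -> float:
        if r <= 0:
            raise InvalidGeometryError(f"bond length must be positive, got {r}")
        return 0.5 * self.k_b * (r - self.r0) ** 2

    def gradient(self, r: float) -> float:
        """dV/dr in kJ/mol/nm."""
        return self.k_b * (r - self.r0)


@dataclass(frozen=True)
class ReBAngleTerm:
    """Restricted-bending angle V(theta) = 1/2 k (cos t - cos t0)^2 / sin^2 t.

    The sin^-2 factor diverges as theta -> 0 or 180 deg, which keeps CG
    triples away from collinearity (where dihedrals become ill defined).
    theta0 in degrees, k_theta in kJ/mol.
    """

    i: int
    j: int
    k: int
    theta0: float
    k_theta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 < 180.0:
            raise ValueError("theta0 must lie strictly inside (0, 180) deg")
        if self.k_theta <= 0:
            raise ValueError("k_theta must be positive")

    def energy(self, theta: float) -> float:
        if theta <= 0.0 or theta >= 180.0:
            raise SingularityError(
                f"ReB potential is singular at theta={theta} deg"
            )
        t = math.radians(theta)
        t0 = math.radians(self.theta0)
        return 0.5 * self.k_theta * (math.cos(t) - math.cos(t0)) ** 2 / math.sin(t) ** 2

    def gradient(self, theta: float) -> float:
        """dV/dtheta with theta in degrees (kJ/mol/deg)."""
        if theta <= 0.0 or theta >= 180.0:
            raise SingularityError(
                f"ReB potential is singular at theta={theta} deg"
            )
        t = math.radians(theta)
        c, s = math.cos(t), math.sin(t)
        c0 = math.cos(math.radians(self.theta0))
        d = c - c0
        # dV/dt = k*d*(-s)/s^2 + 1/2 k d^2 * (-2 cos/sin^3)
        dv_dt = -self.k_theta * d / s - self.k_theta * d * d * c / s**3
        return dv_dt * math.pi / 180.0


@dataclass(frozen=True)
class PeriodicDihedralTerm:
    """Periodic dihedral V(phi) = k_phi (1 + cos(n phi - phi_s)).

    k_phi in kJ/mol, multiplicity n >= 1, phase phi_s in degrees.
    """

    i: int
    j: int
    k: int
    l: int
    k_phi: float
    n: int
    phi_s: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplicity n must be >= 1")
        if self.k_phi < 0:
            raise ValueError("k_phi must be non-negative")

    def energy(self, phi: float) -> float:
        return self.k_phi * (1.0 + math.cos(math.radians(self.n * phi - self.phi_s)))

    def gradient(self, phi: float) -> float:
        """dV/dphi with phi in degrees (kJ/mol/deg)."""
        return (
            -self.k_phi
            * self.n
            * math.sin(math.radians(self.n * phi - self.phi_s))
            * math.pi
            / 180.0
        )


def evaluate_bond_energy(term: HarmonicBondTerm, r: float) -> float:
    """Energy of a harmonic bond at length ``r`` (nm)."""
    return term.energy(r)


def evaluate_reb_angle_energy(term: ReBAngleTerm, theta: float) -> float:
    """Energy of a restricted-bending angle at ``theta`` (deg)."""
    return term.energy(theta)


def evaluate_dihedral_energy(term: PeriodicDihedralTerm, phi: float) -> float:
    """Energy of a periodic dihedral at torsion ``phi`` (deg)."""
    return term.energy(phi)


@dataclass
class CGTopology:
    """A CG molecule: beads, bonded terms, rigid ring groups and bead graph.

    Rigid groups model monosaccharide rings as rigid bodies; beads of the
    same group carry no bonded terms among themselves, and each complete
    group holds one TC4 virtual site at its center of geometry.
    """

    beads: list[Bead]
    bonds: list[HarmonicBondTerm] = field(default_factory=list)
    angles: list[ReBAngleTerm] = field(default_factory=list)
    dihedrals: list[PeriodicDihedralTerm] = field(default_factory=list)
    rigid_groups: dict[int, set[int]] = field(default_factory=dict)
    name: str = "molecule"
    # optional annotations used by the builder / fixtures
    bead_groups: dict[int, str] = field(default_factory=dict)  # bead id -> group
    n_term: int | None = None
    c_term: int | None = None
    glycan_of_bead: dict[int, int] = field(default_factory=dict)
    attachment_residues: dict[int, int] = field(default_factory=dict)  # glycan -> resid
    n_residues: int = 0
    residue_names: dict[int, str] = field(default_factory=dict)

    # -- derived views ----------------------------------------------------

    @property
    def molecule_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(b.id for b in self.beads)
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        # rigid-group members are mutually connected even without bond terms
        for members in self.rigid_groups.values():
            real = sorted(m for m in members if not self.beads_by_id[m].is_virtual)
            for a, b in zip(real, real[1:]):
                g.add_edge(a, b)
        return g

    @property
    def beads_by_id(self) -> dict[int, Bead]:
        return {b.id: b for b in self.beads}

    def coordinates(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.beads))

    def n_glycans(self) -> int:
        return len(set(self.glycan_of_bead.values()))

    def validate_partition(self, heavy_atom_ids: set[str]) -> None:
        """Assert every heavy atom sits in exactly one bead's constituent set."""
        seen: dict[str, int] = {}
        for b in self.beads:
            for a in b.constituent_atoms:
                if a in seen:
                    raise ValueError(f"atom {a} assigned to beads {seen[a]} and {b.id}")
                seen[a] = b.id
        missing = heavy_atom_ids - set(seen)
        if missing:
            raise ValueError(f"unmapped heavy atoms: {sorted(missing)[:5]} ...")
        extra = set(seen) - heavy_atom_ids
        if extra:
            raise ValueError(f"beads reference unknown atoms: {sorted(extra)[:5]} ...")

    def copy(self) -> "CGTopology":
        return CGTopology(
            beads=[replace(b, position=b.position.copy(),
                           constituent_atoms=list(b.constituent_atoms))
                   for b in self.beads],
            bonds=list(self.bonds),
            angles=list(self.angles),
            dihedrals=list(self.dihedrals),
            rigid_groups={k: set(v) for k, v in self.rigid_groups.items()},
            name=self.name,
            bead_groups=dict(self.bead_groups),
            n_term=self.n_term,
            c_term=self.c_term,
            glycan_of_bead=dict(self.glycan_of_bead),
            attachment_residues=dict(self.attachment_residues),
            n_residues=self.n_residues,
            residue_names=dict(self.residue_names),
        )


def net_charge(topology: CGTopology) -> int:
    """Total charge of the molecule in elementary charges."""
    return int(sum(b.charge for b in topology.beads))


class NonbondedParams:
    """Pairwise Lennard-Jones table keyed by unordered bead-type name pairs.

    ``groups`` labels each bead type as protein / glycan / water / ion, which
    the analysis module uses to restrict interaction rescaling to
    protein-protein pairs.
    """

    def __init__(
        self,
        table: dict[tuple[str, str], tuple[float, float]],
        groups: dict[str, str],
    ) -> None:
        self._table: dict[tuple[str, str], tuple[float, float]] = {}
        for (a, b), (sigma, eps) in table.items():
            if eps < 0:
                raise ValueError(f"epsilon must be >= 0 for pair ({a}, {b})")
            self._table[self._key(a, b)] = (float(sigma), float(eps))
        self.groups = dict(groups)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> tuple[float, float]:
        return self._table[self._key(a, b)]

    def pairs(self):
        return self._table.items()

    def copy(self) -> "NonbondedParams":
        return NonbondedParams(dict(self._table), dict(self.groups))

    def set(self, a: str, b: str, sigma: float, eps: float) -> None:
        if eps < 0:
            raise ValueError("epsilon must be >= 0")
        self._table[self._key(a, b)] = (float(sigma), float(eps))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, NonbondedParams)
            and self._table == other._table
            and self.groups == other.groups
        )
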