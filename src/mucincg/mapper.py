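"""Atomistic-to-CG mapping of O-glycosylated peptides.

Maps heavy (non-hydrogen) atoms of an atomistic structure onto MARTINI 3
beads placed at the center of geometry of their constituent atoms, following
the O-glycan conventions used for mucins:

* the glycosidic oxygen connecting two sugars belongs to the glycosyl
  *acceptor* sugar;
* a glycosylated N-acetylhexosamine loses its anomeric hydroxyl and its
  anomeric bead shrinks from SN6 to a TC5 bead holding the -CH-CH- moiety;
* Thr-glycan and Ser-glycan linkages are typed SN4ar and TN4ar;
* sulfated sugars carry a Q4n bead with charge -1;
* each monosaccharide's three ring beads form a rigid group with one TC4
  virtual site at their center of geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .core import (
    Bead,
    BeadType,
    CGTopology,
    HarmonicBondTerm,
    PeriodicDihedralTerm,
    ReBAngleTerm,
    SIZE_CLASS_ATOMS,
)

__all__ = [
    "Atom",
    "AtomisticStructure",
    "TrajectoryFrameSet",
    "BeadTemplate",
    "ResidueTemplate",
    "AttachmentRule",
    "MappingSpec",
    "MappingError",
    "UnmappedResidueError",
    "ConsistencyError",
    "UnsupportedAttachmentError",
    "UnsupportedRingError",
    "map_structure",
    "map_trajectory",
    "apply_glycosidic_linkage",
    "apply_protein_glycan_attachment",
    "add_ring_virtual_sites",
    "read_structure",
    "read_trajectory",
]


class MappingError(ValueError):
    """An atom or template required by the mapping is missing/inconsistent."""


class UnmappedResidueError(MappingError):
    """A residue of the structure has no template in the mapping spec."""


class ConsistencyError(MappingError):
    """A glycosidic-linkage convention is violated."""


class UnsupportedAttachmentError(MappingError):
    """Glycan attachment requested on a residue other than Thr/Ser."""


class UnsupportedRingError(MappingError):
    """A rigid group does not consist of exactly three ring beads."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_id: int
    residue_name: str
    position: np.ndarray  # nm

    @property
    def atom_id(self) -> str:
        return f"{self.residue_id}:{self.name}"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class AtomisticStructure:
    """Heavy-atom structure; ``bonds`` are index pairs into ``atoms``."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] | None = None
    box: np.ndarray | None = None

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[int, str, list[int]]]:
        """(residue_id, residue_name, atom indices) in order of appearance."""
        order: list[int] = []
        info: dict[int, tuple[str, list[int]]] = {}
        for i, a in enumerate(self.atoms):
            if a.residue_id not in info:
                info[a.residue_id] = (a.residue_name, [])
                order.append(a.residue_id)
            info[a.residue_id][1].append(i)
        return [(rid, info[rid][0], info[rid][1]) for rid in order]


@dataclass
class TrajectoryFrameSet:
    """Ordered coordinate frames (atomistic or CG) with box vectors."""

    positions: np.ndarray             # (n_frames, n_sites, 3) nm
    box: np.ndarray | None = None     # (n_frames, 3) nm or None
    dt: float | None = None           # frame spacing metadata (ps)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_sites, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]


# ---------------------------------------------------------------------------
# Mapping specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadTemplate:
    name: str
    type_name: str
    atoms: tuple[str, ...]
    ring: bool = False
    optional: tuple[str, ...] = ()


@dataclass(frozen=True)
class ResidueTemplate:
    resname: str
    beads: tuple[BeadTemplate, ...]
    intra_bonds: tuple[tuple[str, str], ...] = ()
    category: str = "protein"         # "protein" | "sugar"
    anomeric_bead: str | None = None
    anomeric_oh: str | None = None
    hexnac: bool = False
    acceptor_atom: str | None = None


@dataclass(frozen=True)
class AttachmentRule:
    side_bead: str
    link_type: str
    link_atom: str


@dataclass
class MappingSpec:
    """Residue templates + linkage/attachment rules + bead-type table."""

    templates: dict[str, ResidueTemplate]
    bead_types: dict[str, BeadType]
    attachment: dict[str, AttachmentRule] = field(default_factory=dict)
    donor_retype: dict[str, str] = field(
        default_factory=lambda: {"hexnac": "TC5", "default": "TN6"}
    )
    bonded_defaults: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "bond": {"k_b": 5000.0},
            "angle": {"k_theta": 25.0},
            "dihedral": {"k_phi": 1.5, "n": 1, "phi_s": 180.0},
        }
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for tpl in self.templates.values():
            seen: set[str] = set()
            for bt in tpl.beads:
                if bt.type_name not in self.bead_types:
                    raise MappingError(
                        f"{tpl.resname}/{bt.name}: unknown bead type {bt.type_name}"
                    )
                n = len(bt.atoms)
                if not 2 <= n <= 4:
                    raise MappingError(
                        f"{tpl.resname}/{bt.name}: beads hold 2-4 heavy atoms, got {n}"
                    )
                expected = SIZE_CLASS_ATOMS[self.bead_types[bt.type_name].size_class]
                if n != expected:
                    raise MappingError(
                        f"{tpl.resname}/{bt.name}: {self.bead_types[bt.type_name].size_class}"
                        f" bead must hold {expected} atoms, got {n}"
                    )
                dup = seen & set(bt.atoms)
                if dup:
                    raise MappingError(
                        f"{tpl.resname}: atoms {sorted(dup)} appear in multiple beads"
                    )
                seen |= set(bt.atoms)

    def bead_type(self, name: str) -> BeadType:
        return self.bead_types[name]


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """IUPAC torsion angle in degrees, wrapped to (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    phi = float(np.degrees(np.arctan2(y, x)))
    if phi <= -180.0:
        phi += 360.0
    return phi


# ---------------------------------------------------------------------------
# map_structure
# ---------------------------------------------------------------------------


def _enumerate_terms(
    graph: nx.Graph,
    beads: list[Bead],
    coords: dict[int, np.ndarray],
    spec: MappingSpec,
) -> tuple[list[HarmonicBondTerm], list[ReBAngleTerm], list[PeriodicDihedralTerm]]:
    """Instantiate bonded terms from the bead graph.

    Equilibrium values come from the mapped geometry; force constants from
    the spec defaults.  Terms fully inside one rigid group are skipped (rigid
    monosaccharides need no internal bonded terms).
    """
    by_id = {b.id: b for b in beads}

    def same_rigid(ids) -> bool:
        groups = {by_id[i].rigid_group for i in ids}
        return len(groups) == 1 and None not in groups

    bonds: list[HarmonicBondTerm] = []
    for i, j in sorted(tuple(sorted(e)) for e in graph.edges):
        if same_rigid((i, j)):
            continue
        r0 = float(np.linalg.norm(coords[i] - coords[j]))
        bonds.append(HarmonicBondTerm(i, j, r0=max(r0, 1e-3),
                                      k_b=spec.bonded_defaults["bond"]["k_b"]))

    angles: list[ReBAngleTerm] = []
    for j in sorted(graph.nodes):
        nbrs = sorted(graph.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                if same_rigid((i, j, k)):
                    continue
                th = _angle_deg(coords[i], coords[j], coords[k])
                angles.append(
                    ReBAngleTerm(i, j, k, theta0=float(np.clip(th, 5.0, 175.0)),
                                 k_theta=spec.bonded_defaults["angle"]["k_theta"])
                )

    dihedrals: list[PeriodicDihedralTerm] = []
    seen: set[tuple[int, ...]] = set()
    dd = spec.bonded_defaults["dihedral"]
    for j, k in graph.edges:
        for i in graph.neighbors(j):
            if i == k:
                continue
            for l in graph.neighbors(k):
                if l == j or l == i:
                    continue
                key = min((i, j, k, l), (l, k, j, i))
                if key in seen or same_rigid((i, j, k, l)):
                    continue
                seen.add(key)
                dihedrals.append(
                    PeriodicDihedralTerm(*key, k_phi=dd["k_phi"], n=int(dd["n"]),
                                         phi_s=dd["phi_s"])
                )
    dihedrals.sort(key=lambda t: (t.i, t.j, t.k, t.l))
    return bonds, angles, dihedrals


def map_structure(structure: AtomisticStructure, spec: MappingSpec) -> CGTopology:
    """Map an atomistic structure onto a CG topology.

    Each bead sits at the unweighted center of geometry of its constituent
    heavy atoms.  Bead connectivity comes from atom-atom bonds crossing bead
    boundaries when ``structure.bonds`` is given, otherwise from the
    templates' declared intra-residue bonds plus consecutive backbone links.
    """
    positions = structure.positions()
    beads: list[Bead] = []
    atom_to_bead: dict[int, int] = {}
    residue_names: dict[int, str] = {}
    rigid_groups: dict[int, set[int]] = {}
    next_group = 0
    protein_bb: list[int] = []
    n_protein_res = 0

    for rid, resname, atom_idx in structure.residues():
        if resname not in spec.templates:
            raise UnmappedResidueError(f"no template for residue {resname} ({rid})")
        tpl = spec.templates[resname]
        residue_names[rid] = resname
        heavy = {structure.atoms[i].name: i for i in atom_idx
                 if structure.atoms[i].is_heavy}
        assigned: set[str] = set()
        ring_members: list[int] = []
        for bt in tpl.beads:
            idxs = []
            for aname in bt.atoms:
                if aname in heavy:
                    idxs.append(heavy[aname])
                elif aname in bt.optional:
                    continue
                else:
                    raise MappingError(
                        f"residue {resname} ({rid}): atom {aname} required by "
                        f"bead {bt.name} is missing"
                    )
            assigned |= {structure.atoms[i].name for i in idxs}
            bead_id = len(beads)
            bead = Bead(
                id=bead_id,
                bead_type=spec.bead_type(bt.type_name),
                position=positions[idxs].mean(axis=0),
                constituent_atoms=[structure.atoms[i].atom_id for i in idxs],
                residue_id=rid,
                name=bt.name,
            )
            beads.append(bead)
            for i in idxs:
                atom_to_bead[i] = bead_id
            if bt.ring:
                ring_members.append(bead_id)
        unassigned = set(heavy) - assigned
        if unassigned:
            raise MappingError(
                f"residue {resname} ({rid}): heavy atoms {sorted(unassigned)} "
                f"not covered by any bead template"
            )
        if ring_members:
            rigid_groups[next_group] = set(ring_members)
            for b in ring_members:
                beads[b].rigid_group = next_group
            next_group += 1
        if tpl.category == "protein":
            n_protein_res += 1
            bb = next((b.id for b in beads[-len(tpl.beads):] if b.name == "BB"),
                      None)
            if bb is not None:
                protein_bb.append(bb)

    # bead connectivity
    graph = nx.Graph()
    graph.add_nodes_from(b.id for b in beads)
    if structure.bonds is not None:
        for i, j in structure.bonds:
            bi, bj = atom_to_bead.get(i), atom_to_bead.get(j)
            if bi is None or bj is None or bi == bj:
                continue
            graph.add_edge(bi, bj)
    else:
        name_to_id = {(b.residue_id, b.name): b.id for b in beads}
        for rid, resname, _ in structure.residues():
            for a, b in spec.templates[resname].intra_bonds:
                graph.add_edge(name_to_id[(rid, a)], name_to_id[(rid, b)])
        for a, b in zip(protein_bb, protein_bb[1:]):
            graph.add_edge(a, b)

    coords = {b.id: b.position for b in beads}
    bonds, angles, dihedrals = _enumerate_terms(graph, beads, coords, spec)

    topo = CGTopology(
        beads=beads,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        rigid_groups=rigid_groups,
        name="mapped",
        n_term=protein_bb[0] if protein_bb else None,
        c_term=protein_bb[-1] if protein_bb else None,
        n_residues=n_protein_res,
        residue_names=residue_names,
    )
    _assign_groups(topo, spec)
    heavy_ids = {structure.atoms[i].atom_id for i in structure.heavy_indices()}
    topo.validate_partition(heavy_ids)
    return topo


def _assign_groups(topo: CGTopology, spec: MappingSpec) -> None:
    """Label beads protein/glycan by their residue template category."""
    for b in topo.beads:
        tpl = spec.templates.get(topo.residue_names.get(b.residue_id, ""), None)
        topo.bead_groups[b.id] = (
            "glycan" if (tpl is not None and tpl.category == "sugar") else "protein"
        )


def map_trajectory(
    frames: TrajectoryFrameSet, structure: AtomisticStructure, spec: MappingSpec
) -> TrajectoryFrameSet:
    """Reduce an atomistic trajectory to pseudo-CG bead coordinates."""
    if frames.n_sites != len(structure.atoms):
        raise ValueError(
            f"trajectory has {frames.n_sites} atoms but structure has "
            f"{len(structure.atoms)}"
        )
    topo = map_structure(structure, spec)
    id_of = {a.atom_id: i for i, a in enumerate(structure.atoms)}
    out = np.empty((frames.n_frames, len(topo.beads), 3))
    for b in topo.beads:
        idxs = [id_of[a] for a in b.constituent_atoms]
        out[:, b.id, :] = frames.positions[:, idxs, :].mean(axis=1)
    return TrajectoryFrameSet(out, box=frames.box, dt=frames.dt)


# ---------------------------------------------------------------------------
# Linkage operations
# ---------------------------------------------------------------------------


def _find_bead(topo: CGTopology, residue_id: int, bead_name: str) -> Bead:
    for b in topo.beads:
        if b.residue_id == residue_id and b.name == bead_name:
            return b
    raise MappingError(f"no bead {bead_name} in residue {residue_id}")


def _owning_bead(topo: CGTopology, atom_id: str) -> Bead | None:
    for b in topo.beads:
        if atom_id in b.constituent_atoms:
            return b
    return None


def _retype_donor_anomeric(
    topo: CGTopology, donor_id: int, spec: MappingSpec,
    structure: AtomisticStructure | None = None,
) -> None:
    tpl = spec.templates[topo.residue_names[donor_id]]
    if tpl.anomeric_bead is None:
        raise MappingError(f"residue {tpl.resname} has no anomeric bead")
    bead = _find_bead(topo, donor_id, tpl.anomeric_bead)
    oh_id = f"{donor_id}:{tpl.anomeric_oh}"
    if oh_id in bead.constituent_atoms:
        if structure is None:
            raise MappingError(
                f"donor {donor_id} still holds its anomeric hydroxyl {oh_id}; "
                "pass the structure so the bead can be recomputed"
            )
        bead.constituent_atoms.remove(oh_id)
        keep = [i for i, a in enumerate(structure.atoms)
                if a.atom_id in bead.constituent_atoms]
        bead.position = structure.positions()[keep].mean(axis=0)
    new_type = spec.donor_retype["hexnac" if tpl.hexnac else "default"]
    bead.bead_type = spec.bead_type(new_type)


def apply_glycosidic_linkage(
    topology: CGTopology,
    donor_sugar_id: int,
    acceptor_sugar_id: int,
    spec: MappingSpec,
    structure: AtomisticStructure | None = None,
) -> CGTopology:
    """Enforce the glycosidic conventions on a mapped sugar-sugar linkage.

    The bridging oxygen must live in a bead of the acceptor sugar; the donor
    anomeric bead loses its hydroxyl oxygen and is retyped (TC5 for
    N-acetylhexosamines, TN6 otherwise).
    """
    topo = topology.copy()
    residue_names = topo.residue_names
    acc_tpl = spec.templates[residue_names[acceptor_sugar_id]]
    if acc_tpl.acceptor_atom is None:
        raise ConsistencyError(
            f"residue {acc_tpl.resname} declares no glycosyl-acceptor atom"
        )
    bridge_id = f"{acceptor_sugar_id}:{acc_tpl.acceptor_atom}"
    owner = _owning_bead(topo, bridge_id)
    if owner is None:
        raise ConsistencyError(f"bridging oxygen {bridge_id} not found in any bead")
    if owner.residue_id == donor_sugar_id:
        raise ConsistencyError(
            f"bridging oxygen {bridge_id} is assigned to the donor sugar; "
            "it must belong to the acceptor"
        )
    if owner.residue_id != acceptor_sugar_id:
        raise ConsistencyError(
            f"bridging oxygen {bridge_id} belongs to residue {owner.residue_id}, "
            f"not the acceptor {acceptor_sugar_id}"
        )
    _retype_donor_anomeric(topo, donor_sugar_id, spec, structure)
    don_tpl = spec.templates[residue_names[donor_sugar_id]]
    ano = _find_bead(topo, donor_sugar_id, don_tpl.anomeric_bead)
    if not any({t.i, t.j} == {ano.id, owner.id} for t in topo.bonds):
        r0 = float(np.linalg.norm(ano.position - owner.position))
        topo.bonds.append(
            HarmonicBondTerm(*sorted((ano.id, owner.id)), r0=max(r0, 1e-3),
                             k_b=spec.bonded_defaults["bond"]["k_b"])
        )
    return topo


def apply_protein_glycan_attachment(
    topology: CGTopology,
    residue_id: int,
    glycan_id: int,
    spec: MappingSpec,
    structure: AtomisticStructure | None = None,
) -> CGTopology:
    """Type the Thr/Ser-glycan linkage bead and adjust the glycan root.

    ``glycan_id`` is the residue id of the glycan's root sugar (the glycosyl
    donor to the side-chain oxygen).
    """
    topo = topology.copy()
    residue_names = topo.residue_names
    resname = residue_names.get(residue_id)
    if resname not in spec.attachment:
        raise UnsupportedAttachmentError(
            f"O-glycan attachment is supported on Thr/Ser only, got "
            f"{resname} ({residue_id})"
        )
    rule = spec.attachment[resname]
    side = _find_bead(topo, residue_id, rule.side_bead)
    side.bead_type = spec.bead_type(rule.link_type)
    _retype_donor_anomeric(topo, glycan_id, spec, structure)
    root_tpl = spec.templates[residue_names[glycan_id]]
    ano = _find_bead(topo, glycan_id, root_tpl.anomeric_bead)
    if not any({t.i, t.j} == {ano.id, side.id} for t in topo.bonds):
        r0 = float(np.linalg.norm(ano.position - side.position))
        topo.bonds.append(
            HarmonicBondTerm(*sorted((ano.id, side.id)), r0=max(r0, 1e-3),
                             k_b=spec.bonded_defaults["bond"]["k_b"])
        )
    topo.attachment_residues[glycan_id] = residue_id
    for b in topo.beads:
        if b.residue_id == glycan_id:
            topo.glycan_of_bead[b.id] = glycan_id
    return topo


def add_ring_virtual_sites(topology: CGTopology) -> CGTopology:
    """Append one TC4 virtual site at the centroid of each 3-bead rigid ring.

    Re-applying is a no-op: groups that already contain a virtual site are
    left untouched.
    """
    topo = topology.copy()
    by_id = topo.beads_by_id
    tc4 = BeadType("TC4", "T")
    for gid in sorted(topo.rigid_groups):
        members = topo.rigid_groups[gid]
        if any(by_id[m].is_virtual for m in members):
            continue
        if len(members) != 3:
            raise UnsupportedRingError(
                f"rigid group {gid} has {len(members)} beads; monosaccharide "
                "rings map to exactly 3"
            )
        centroid = np.mean([by_id[m].position for m in sorted(members)], axis=0)
        ref = by_id[min(members)]
        vs = Bead(
            id=len(topo.beads),
            bead_type=tc4,
            position=centroid,
            constituent_atoms=[],
            is_virtual=True,
            rigid_group=gid,
            residue_id=ref.residue_id,
            name="VS",
        )
        topo.beads.append(vs)
        topo.rigid_groups[gid] = set(members) | {vs.id}
        topo.bead_groups[vs.id] = topo.bead_groups.get(ref.id, "glycan")
        if ref.id in topo.glycan_of_bead:
            topo.glycan_of_bead[vs.id] = topo.glycan_of_bead[ref.id]
    return topo


# ---------------------------------------------------------------------------
# File readers (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def read_structure(path: str | Path) -> AtomisticStructure:
    """Read a PDB or GRO structure into nm coordinates (bonds if present)."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = []
        for a in u.atoms:
            try:
                element = a.element if a.element else a.name[0]
            except Exception:
                element = a.name[0]
            atoms.append(
                Atom(
                    name=a.name,
                    element=element,
                    residue_id=int(a.resid),
                    residue_name=a.resname.strip(),
                    position=np.asarray(a.position, dtype=float) / 10.0,
                )
            )
        bonds = None
        if hasattr(u, "bonds") and len(u.bonds):
            bonds = [(int(b.atoms[0].index), int(b.atoms[1].index)) for b in u.bonds]
        box = None
        if u.dimensions is not None and u.dimensions[:3].any():
            box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    return AtomisticStructure(atoms=atoms, bonds=bonds, box=box)


def read_trajectory(topology_path: str | Path, traj_path: str | Path | None = None) -> TrajectoryFrameSet:
    """Read a (multi-frame) trajectory into nm coordinates."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = (mda.Universe(str(topology_path), str(traj_path))
             if traj_path else mda.Universe(str(topology_path)))
        frames, boxes = [], []
        for ts in u.trajectory:
            frames.append(u.atoms.positions.copy() / 10.0)
            boxes.append(ts.dimensions[:3] / 10.0 if ts.dimensions is not None else None)
    box = None
    if all(b is not None for b in boxes) and boxes:
        box = np.asarray(boxes, dtype=float)
    return TrajectoryFrameSet(np.asarray(frames), box=box)
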