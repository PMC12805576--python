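"""Synthetic inputs: toy glycopeptides, the packaged Mini2 construct,
Boltzmann-distributed trajectories and a desk-scale Monte-Carlo sampler.

Everything here is generated programmatically so the rest of the toolkit is
testable without MD engines or downloads.  The pseudo-atomistic structures
place 2-4 pseudo-atoms at fixed offsets around each bead center -- they are
mapping-consistent by construction, not chemically realistic.  The packaged
Mini2 composition is a documented synthetic stand-in with the published
counts (30 residues, 18 O-glycans, net charge -13 e).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    KB,
    Bead,
    BeadType,
    CGTopology,
    HarmonicBondTerm,
    PeriodicDihedralTerm,
    ReBAngleTerm,
)
from .mapper import (
    Atom,
    AtomisticStructure,
    TrajectoryFrameSet,
    add_ring_virtual_sites,
    apply_glycosidic_linkage,
    apply_protein_glycan_attachment,
    map_structure,
)
from .tables import default_mapping_spec, load_mini2_composition

__all__ = [
    "GlycanTree",
    "SamplerConfig",
    "MCResult",
    "UnsupportedTopologyError",
    "StuckSamplerError",
    "build_glycopeptide",
    "generate_toy_glycopeptide",
    "build_mini2_construct",
    "split_into_fragments",
    "generate_synthetic_trajectory",
    "mc_sample_molecule",
    "brush_chain",
    "flory_scaling_demo",
]

_ONE_LETTER = {"G": "GLY", "P": "PRO", "S": "SER", "T": "THR", "H": "HIS"}


class UnsupportedTopologyError(ValueError):
    """The bead graph has cycles outside rigid groups."""


class StuckSamplerError(RuntimeError):
    """The Metropolis sampler accepted no moves over its probe window."""


@dataclass
class GlycanTree:
    """One O-glycan: sugar residues plus donor->acceptor linkages."""

    name: str
    sugars: list[tuple[int, str]]             # (local id, residue template name)
    linkages: list[tuple[int, int, str]]      # (donor local id, acceptor, label)
    root: int

    def __post_init__(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(i for i, _ in self.sugars)
        g.add_edges_from((d, a) for d, a, _ in self.linkages)
        if not nx.is_tree(g):
            raise ValueError(f"glycan {self.name} is not a tree")

    @classmethod
    def from_dict(cls, name: str, raw: dict) -> "GlycanTree":
        return cls(
            name=name,
            sugars=[(s["id"], s["resname"]) for s in raw["sugars"]],
            linkages=[(l["donor"], l["acceptor"], l.get("label", ""))
                      for l in raw.get("linkages", [])],
            root=raw["root"],
        )


# ---------------------------------------------------------------------------
# Pseudo-atomistic structure generation
# ---------------------------------------------------------------------------

# zero-mean offset patterns (nm) for 2/3/4 pseudo-atoms around a bead center
_OFFSETS = {
    2: np.array([[0.06, 0.0, 0.0], [-0.06, 0.0, 0.0]]),
    3: np.array([[0.07, 0.0, 0.0], [-0.035, 0.06, 0.0], [-0.035, -0.06, 0.0]]),
    4: np.array([[0.06, 0.06, 0.06], [0.06, -0.06, -0.06],
                 [-0.06, 0.06, -0.06], [-0.06, -0.06, 0.06]]),
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_glycopeptide(
    sequence: list[str],
    glycans: list[tuple[int, str]],
    trees: dict[str, GlycanTree] | None = None,
    spec=None,
    seed: int = 0,
    name: str = "glycopeptide",
) -> tuple[AtomisticStructure, CGTopology]:
    """Generate a pseudo-atomistic glycopeptide and its ground-truth topology.

    ``sequence`` lists residue template names (GLY/PRO/SER/THR/HIS);
    ``glycans`` lists (1-based residue index, tree name).  Deterministic for
    a fixed seed.
    """
    if spec is None:
        spec = default_mapping_spec()
    if trees is None:
        trees = packaged_trees()
    rng = np.random.default_rng(seed)
    n_res = len(sequence)
    if n_res < 1:
        raise ValueError("sequence must have at least one residue")
    sites = {site for site, _ in glycans}
    for site in sites:
        if not 1 <= site <= n_res:
            raise ValueError(f"glycosylation site {site} outside the sequence")
        if sequence[site - 1] not in spec.attachment:
            raise ValueError(
                f"site {site} is {sequence[site - 1]}; O-glycans attach to "
                f"{sorted(spec.attachment)}"
            )
    if len(sites) != len(glycans):
        raise ValueError("duplicate glycosylation sites")

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    atom_index: dict[str, int] = {}

    def add_bead_atoms(rid: int, resname: str, bead_tpl, center: np.ndarray,
                      skip: set[str] = frozenset()) -> None:
        names = [a for a in bead_tpl.atoms if a not in skip]
        off = _OFFSETS[len(names)] @ _random_rotation(rng).T
        prev = None
        for aname, o in zip(names, off):
            idx = len(atoms)
            atoms.append(Atom(name=aname, element=aname[0], residue_id=rid,
                              residue_name=resname, position=center + o))
            atom_index[f"{rid}:{aname}"] = idx
            if prev is not None:
                bonds.append((prev, idx))
            prev = idx

    def link(rid_a: int, aname_a: str, rid_b: int, aname_b: str) -> None:
        bonds.append((atom_index[f"{rid_a}:{aname_a}"],
                      atom_index[f"{rid_b}:{aname_b}"]))

    # protein backbone along x, side chains in +y
    side_centers: dict[int, np.ndarray] = {}
    for i, letter_or_name in enumerate(sequence):
        resname = _ONE_LETTER.get(letter_or_name, letter_or_name)
        rid = i + 1
        tpl = spec.templates[resname]
        bb_center = np.array([0.35 * i, 0.0, 0.0])
        for k, bt in enumerate(tpl.beads):
            if bt.name == "BB":
                center = bb_center
            else:
                center = bb_center + np.array([0.08 * (k - 1), 0.26 * k, 0.0])
            if bt.name == "SC1":
                side_centers[rid] = center
            add_bead_atoms(rid, resname, bt, center)
        if i > 0:
            link(rid - 1, "C", rid, "N")
        for a, b in tpl.intra_bonds:
            tpl_by_name = {t.name: t for t in tpl.beads}
            link(rid, tpl_by_name[a].atoms[0], rid, tpl_by_name[b].atoms[0])

    # glycans stacked above their attachment site
    next_rid = n_res + 1
    glycan_residues: dict[int, list[int]] = {}      # root rid -> all tree rids
    attach_of_root: dict[int, int] = {}
    linkage_pairs: list[tuple[int, int]] = []       # (donor rid, acceptor rid)
    for site, tree_name in sorted(glycans):
        tree = trees[tree_name]
        rid_of = {local: next_rid + k for k, (local, _) in enumerate(tree.sugars)}
        resname_of = dict(tree.sugars)
        next_rid += len(tree.sugars)
        # depth of each sugar from the root along the tree
        depth = {tree.root: 0}
        children: dict[int, list[int]] = {}
        g = nx.Graph()
        g.add_edges_from((d, a) for d, a, _ in tree.linkages)
        g.add_nodes_from(rid_of)
        for parent, child in nx.bfs_edges(g, tree.root):
            depth[child] = depth[parent] + 1
            children.setdefault(parent, []).append(child)
        base = side_centers[site] + np.array([0.0, 0.55, 0.0])
        lateral: dict[int, float] = {tree.root: 0.0}
        for parent in depth:
            for k, child in enumerate(children.get(parent, [])):
                lateral[child] = lateral[parent] + 0.3 * (k - 0.5 * (len(children[parent]) - 1))
        for local, resname in tree.sugars:
            rid = rid_of[local]
            tpl = spec.templates[resname]
            center = base + np.array([lateral.get(local, 0.0),
                                      0.6 * depth.get(local, 0), 0.0])
            ring_pattern = {
                tpl.beads[0].name: np.array([-0.12, -0.07, 0.0]),
                tpl.beads[1].name: np.array([0.12, -0.07, 0.0]),
                tpl.beads[2].name: np.array([0.0, 0.14, 0.0]),
            }
            is_donor_here = True  # every sugar in a tree donates (root to protein)
            skip = {tpl.anomeric_oh} if (tpl.anomeric_oh and is_donor_here) else set()
            extra = 0
            for bt in tpl.beads:
                if bt.name in ring_pattern:
                    c = center + ring_pattern[bt.name]
                else:
                    extra += 1
                    c = center + np.array([0.28, 0.1 * extra - 0.15, 0.12])
                add_bead_atoms(rid, resname, bt,
                               c, skip=skip if bt.name == tpl.anomeric_bead else set())
            for a, b in tpl.intra_bonds:
                tpl_by_name = {t.name: t for t in tpl.beads}
                a_atoms = [x for x in tpl_by_name[a].atoms
                           if f"{rid}:{x}" in atom_index]
                b_atoms = [x for x in tpl_by_name[b].atoms
                           if f"{rid}:{x}" in atom_index]
                link(rid, a_atoms[0], rid, b_atoms[0])
        # glycosidic atom bonds: donor anomeric carbon -> acceptor bridging O
        for donor, acceptor, _ in tree.linkages:
            d_tpl = spec.templates[resname_of[donor]]
            a_tpl = spec.templates[resname_of[acceptor]]
            link(rid_of[donor], d_tpl.beads[
                [b.name for b in d_tpl.beads].index(d_tpl.anomeric_bead)].atoms[0],
                rid_of[acceptor], a_tpl.acceptor_atom)
            linkage_pairs.append((rid_of[donor], rid_of[acceptor]))
        # attachment bond: side-chain oxygen -> root anomeric carbon
        root_rid = rid_of[tree.root]
        root_tpl = spec.templates[resname_of[tree.root]]
        rule = spec.attachment[_ONE_LETTER.get(sequence[site - 1], sequence[site - 1])]
        link(site, rule.link_atom, root_rid, root_tpl.beads[
            [b.name for b in root_tpl.beads].index(root_tpl.anomeric_bead)].atoms[0])
        glycan_residues[root_rid] = sorted(rid_of.values())
        attach_of_root[root_rid] = site

    structure = AtomisticStructure(atoms=atoms, bonds=bonds)
    topo = map_structure(structure, spec)
    topo.name = name
    for root_rid, site in attach_of_root.items():
        topo = apply_protein_glycan_attachment(topo, site, root_rid, spec)
    for donor_rid, acceptor_rid in linkage_pairs:
        topo = apply_glycosidic_linkage(topo, donor_rid, acceptor_rid, spec)
    for root_rid, rids in glycan_residues.items():
        rid_set = set(rids)
        for b in topo.beads:
            if b.residue_id in rid_set:
                topo.glycan_of_bead[b.id] = root_rid
        topo.attachment_residues[root_rid] = attach_of_root[root_rid]
    topo = add_ring_virtual_sites(topo)
    topo.name = name
    return structure, topo


def packaged_trees(composition: dict | None = None) -> dict[str, GlycanTree]:
    if composition is None:
        composition = load_mini2_composition()
    return {name: GlycanTree.from_dict(name, raw)
            for name, raw in composition["trees"].items()}


def generate_toy_glycopeptide(
    n_residues: int,
    glycan_pattern: list[tuple[int, str]] | None = None,
    seed: int = 0,
):
    """Small test glycopeptide: (structure, mapping spec, ground-truth topology).

    The backbone cycles Thr/Ser/Pro/Gly; ``glycan_pattern`` lists (site,
    tree name) pairs using the packaged glycan trees.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    spec = default_mapping_spec()
    cycle = ["THR", "SER", "PRO", "GLY"]
    sequence = [cycle[i % 4] for i in range(n_residues)]
    glycans = list(glycan_pattern or [])
    for site, _ in glycans:
        if not 1 <= site <= n_residues:
            raise ValueError(
                f"glycosylation site {site} outside the {n_residues}-residue "
                "sequence")
        if sequence[site - 1] not in spec.attachment:
            sequence[site - 1] = "THR"
    structure, topo = build_glycopeptide(
        sequence, glycans, spec=spec, seed=seed, name=f"toy{n_residues}"
    )
    return structure, spec, topo


def build_mini2_construct(composition: dict | None = None, seed: int = 0) -> CGTopology:
    """CG topology of the packaged (synthetic-composition) Mini2 construct.

    30 backbone residues, 18 O-glycan trees on Thr/Ser, net charge -13 e.
    """
    if composition is None:
        composition = load_mini2_composition()
    for key in ("sequence", "glycans", "trees"):
        if key not in composition:
            raise KeyError(f"composition table lacks the {key!r} entry")
    sequence = [_ONE_LETTER[c] for c in composition["sequence"]]
    glycans = [(g["site"], g["tree"]) for g in composition["glycans"]]
    trees = packaged_trees(composition)
    _, topo = build_glycopeptide(sequence, glycans, trees=trees, seed=seed,
                                 name=composition.get("name", "MINI2"))
    return topo


def split_into_fragments(construct: CGTopology, fragment_length: int) -> list[CGTopology]:
    """One fragment per glycan: ``fragment_length`` backbone residues centered
    on the attachment site (clamped at the chain ends) plus that glycan."""
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if fragment_length > construct.n_residues:
        raise ValueError(
            f"fragment_length {fragment_length} exceeds the construct's "
            f"{construct.n_residues} residues"
        )
    if not construct.attachment_residues:
        raise ValueError("construct carries no glycan attachment map")
    half = (fragment_length - 1) // 2
    fragments = []
    for gid, site in sorted(construct.attachment_residues.items(),
                            key=lambda kv: kv[1]):
        start = min(max(1, site - half), construct.n_residues - fragment_length + 1)
        window = set(range(start, start + fragment_length))
        glycan_rids = {construct.beads_by_id[b].residue_id
                       for b, g in construct.glycan_of_bead.items() if g == gid}
        keep = [b for b in construct.beads
                if (b.residue_id in window and b.id not in construct.glycan_of_bead)
                or construct.glycan_of_bead.get(b.id) == gid]
        old_ids = [b.id for b in keep]
        new_id = {o: i for i, o in enumerate(old_ids)}
        frag = CGTopology(beads=[], name=f"{construct.name}-frag{site}")
        from dataclasses import replace as _replace

        for b in keep:
            frag.beads.append(_replace(
                b, id=new_id[b.id], position=b.position.copy(),
                constituent_atoms=list(b.constituent_atoms)))
        inside = set(old_ids)
        frag.bonds = [HarmonicBondTerm(new_id[t.i], new_id[t.j], t.r0, t.k_b)
                      for t in construct.bonds if {t.i, t.j} <= inside]
        frag.angles = [ReBAngleTerm(new_id[t.i], new_id[t.j], new_id[t.k],
                                    t.theta0, t.k_theta)
                       for t in construct.angles if {t.i, t.j, t.k} <= inside]
        frag.dihedrals = [
            PeriodicDihedralTerm(new_id[t.i], new_id[t.j], new_id[t.k],
                                 new_id[t.l], t.k_phi, t.n, t.phi_s)
            for t in construct.dihedrals if {t.i, t.j, t.k, t.l} <= inside]
        for g, members in construct.rigid_groups.items():
            if members <= inside:
                frag.rigid_groups[g] = {new_id[m] for m in members}
        # reindex rigid-group labels on the beads
        for b in frag.beads:
            if b.rigid_group is not None and b.rigid_group not in frag.rigid_groups:
                b.rigid_group = None
        frag.bead_groups = {new_id[b]: g for b, g in construct.bead_groups.items()
                            if b in inside}
        frag.glycan_of_bead = {new_id[b]: g for b, g in
                               construct.glycan_of_bead.items()
                               if b in inside and g == gid}
        frag.attachment_residues = {gid: site}
        frag.residue_names = {r: n for r, n in construct.residue_names.items()
                              if r in window or r in glycan_rids}
        frag.n_residues = fragment_length
        bbs = [b.id for b in frag.beads if b.name == "BB"]
        frag.n_term = bbs[0] if bbs else None
        frag.c_term = bbs[-1] if bbs else None
        fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# Synthetic Boltzmann trajectories (exact per-degree-of-freedom sampling)
# ---------------------------------------------------------------------------


def _super_tree(topology: CGTopology):
    """Collapse rigid groups to supernodes and verify the result is a tree."""
    group_of = {b.id: b.rigid_group for b in topology.beads}

    def snode(i):
        return ("g", group_of[i]) if group_of[i] is not None else ("b", i)

    g = topology.molecule_graph
    sg = nx.Graph()
    for i in g.nodes:
        sg.add_node(snode(i))
    for i, j in g.edges:
        si, sj = snode(i), snode(j)
        if si == sj:
            continue
        if sg.has_edge(si, sj):
            raise UnsupportedTopologyError(
                "multiple connections between the same units form a cycle"
            )
        sg.add_edge(si, sj, beads=(i, j))
    if sg.number_of_nodes() and not nx.is_tree(sg):
        raise UnsupportedTopologyError(
            "bead graph has cycles outside rigid groups; cannot build a "
            "spanning set of internal coordinates"
        )
    return sg, snode


def _angle_grid_sample(theta0, k_theta, T, size, rng):
    grid = np.arange(0.05, 180.0, 0.05)
    t = np.radians(grid)
    v = 0.5 * k_theta * (np.cos(t) - math.cos(math.radians(theta0))) ** 2 / np.sin(t) ** 2
    p = np.sin(t) * np.exp(-(v - v.min()) / (KB * T))
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, grid)


def _dihedral_grid_sample(k_phi, n, phi_s, T, size, rng):
    grid = np.arange(-179.95, 180.0, 0.1)
    v = k_phi * (1.0 + np.cos(np.radians(n * grid - phi_s)))
    p = np.exp(-(v - v.min()) / (KB * T))
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, grid)


def _nerf_place(A, B, C, r, theta_deg, phi_deg):
    """Vectorized natural-extension placement of D given A-B-C and internals.

    All of A/B/C are (F,3); r/theta/phi are (F,) arrays.  The torsion
    convention matches the IUPAC sign measured by the analysis routines.
    """
    t = np.radians(theta_deg)
    p = np.radians(phi_deg)
    bc = C - B
    bc /= np.linalg.norm(bc, axis=1)[:, None]
    ab = B - A
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=1)[:, None]
    m = np.cross(n, bc)
    d2 = np.stack([-r * np.cos(t), r * np.sin(t) * np.cos(p),
                   -r * np.sin(t) * np.sin(p)], axis=1)
    return C + d2[:, [0]] * bc + d2[:, [1]] * m + d2[:, [2]] * n


def generate_synthetic_trajectory(
    topology: CGTopology,
    T: float = 300.0,
    n_frames: int = 1000,
    seed: int = 0,
) -> TrajectoryFrameSet:
    """Frames whose bonded degrees of freedom follow exact Boltzmann densities.

    Bonds are Gaussian around r0 with sd sqrt(kB*T/k_b); angles follow
    sin(theta) exp(-V_ReB/kBT); dihedrals follow exp(-V/kBT).  Coordinates
    are rebuilt chain-wise (natural-extension), rigid groups are reproduced
    with frozen internal geometry and random orientation.  Degrees of
    freedom without a matching bonded term are held at the reference
    geometry.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    sg, snode = _super_tree(topology)
    by_id = topology.beads_by_id
    ref = topology.coordinates()
    F, N = n_frames, len(topology.beads)
    pos = np.full((F, N, 3), np.nan)
    placed: list[int] = []

    bond_of = {frozenset((t.i, t.j)): t for t in topology.bonds}
    angle_of = {}
    for t in topology.angles:
        angle_of[(t.j, frozenset((t.i, t.k)))] = t
    dihedral_of = {}
    for t in topology.dihedrals:
        dihedral_of[(t.i, t.j, t.k, t.l)] = t
        dihedral_of[(t.l, t.k, t.j, t.i)] = t

    graph = topology.molecule_graph
    parent: dict[int, int | None] = {}

    def place_group(gid: int, anchor: int | None, anchor_pos: np.ndarray | None):
        members = sorted(topology.rigid_groups[gid])
        if anchor is None:
            anchor = members[0]
            anchor_pos = np.broadcast_to(ref[anchor], (F, 3)).copy()
            rot = np.broadcast_to(np.eye(3), (F, 3, 3))
        else:
            rot = np.stack([_random_rotation(rng) for _ in range(F)])
        for m in members:
            offset = ref[m] - ref[anchor]
            pos[:, m, :] = anchor_pos + np.einsum("fij,j->fi", rot, offset)
            placed.append(m)
            parent.setdefault(m, anchor if m != anchor else parent.get(anchor))

    def sample_bond(p_bead: int, c_bead: int) -> np.ndarray:
        t = bond_of.get(frozenset((p_bead, c_bead)))
        if t is None:
            return np.full(F, float(np.linalg.norm(ref[c_bead] - ref[p_bead])))
        sd = math.sqrt(KB * T / t.k_b)
        return rng.normal(t.r0, sd, F)

    def sample_angle(g_bead: int, p_bead: int, c_bead: int) -> np.ndarray:
        t = angle_of.get((p_bead, frozenset((g_bead, c_bead))))
        if t is None:
            from .mapper import _angle_deg

            return np.full(F, _angle_deg(ref[g_bead], ref[p_bead], ref[c_bead]))
        return _angle_grid_sample(t.theta0, t.k_theta, T, F, rng)

    def sample_dihedral(gg: int | None, g_bead: int, p_bead: int,
                        c_bead: int) -> np.ndarray:
        if gg is None:
            return np.zeros(F)
        t = dihedral_of.get((gg, g_bead, p_bead, c_bead))
        if t is None:
            from .mapper import dihedral_deg

            return np.full(F, dihedral_deg(ref[gg], ref[g_bead], ref[p_bead],
                                           ref[c_bead]))
        return _dihedral_grid_sample(t.k_phi, t.n, t.phi_s, T, F, rng)

    # choose a root supernode (the N-terminus when available)
    root_bead = topology.n_term if topology.n_term is not None else (
        topology.beads[0].id if topology.beads else None)
    if root_bead is None:
        return TrajectoryFrameSet(np.zeros((F, 0, 3)))
    root = snode(root_bead)

    if root[0] == "g":
        place_group(root[1], None, None)
    else:
        pos[:, root[1], :] = 0.0
        placed.append(root[1])
        parent[root[1]] = None

    for parent_s, child_s in nx.bfs_edges(sg, root):
        p_bead, c_bead = sg.edges[parent_s, child_s]["beads"]
        if snode(p_bead) != parent_s:
            p_bead, c_bead = c_bead, p_bead
        # anchor chain: grandparent g and great-grandparent gg among placed
        g_bead = parent.get(p_bead)
        if g_bead is None:
            g_bead = next((n for n in graph.neighbors(p_bead) if n in placed
                           and n != c_bead), None)
        gg_bead = parent.get(g_bead) if g_bead is not None else None
        if gg_bead in (p_bead, c_bead):
            gg_bead = None
        if g_bead is not None and gg_bead is None:
            gg_bead = next((n for n in graph.neighbors(g_bead)
                            if n in placed and n not in (p_bead, c_bead)), None)

        r = sample_bond(p_bead, c_bead)
        if g_bead is None:
            # second site of the chain: extend along +x
            pos[:, c_bead, :] = pos[:, p_bead, :] + np.stack(
                [r, np.zeros(F), np.zeros(F)], axis=1)
        else:
            theta = sample_angle(g_bead, p_bead, c_bead)
            phi = sample_dihedral(gg_bead, g_bead, p_bead, c_bead)
            A = (pos[:, gg_bead, :] if gg_bead is not None
                 else pos[:, g_bead, :] + np.array([0.0, 0.0, 1.0]))
            pos[:, c_bead, :] = _nerf_place(A, pos[:, g_bead, :],
                                            pos[:, p_bead, :], r, theta, phi)
        placed.append(c_bead)
        parent[c_bead] = p_bead
        if child_s[0] == "g":
            place_group(child_s[1], c_bead, pos[:, c_bead, :])

    if np.isnan(pos).any():
        raise UnsupportedTopologyError("disconnected beads could not be placed")
    return TrajectoryFrameSet(pos)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Settings for the desk-scale Metropolis sampler."""

    temperature: float = 300.0
    step: float = 0.06                # nm, single-bead displacement half-width
    n_steps: int = 50_000
    seed: int = 0
    excluded_volume: bool = False     # WCA-style soft repulsion surrogate
    sample_every: int = 50
    pivot_prob: float = 0.0           # fraction of pivot (subtree rotation) moves
    wca_epsilon: float = 2.5          # kJ/mol
    wca_sigma_scale: float = 1.0      # sigma_ij = scale * (r_i + r_j)
    backbone_attraction: float = 0.0  # kJ/mol; full LJ between backbone beads
    probe_window: int = 10_000        # stuck-sampler detection window

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class MCResult:
    frames: TrajectoryFrameSet
    acceptance_rate: float
    n_steps: int
    energies: np.ndarray


class _EnergyModel:
    """Vectorized bonded + optional WCA energy of one molecule."""

    def __init__(self, topology: CGTopology, config: SamplerConfig):
        self.kT = KB * config.temperature
        b = topology.bonds
        self.b_ij = np.array([[t.i, t.j] for t in b], dtype=int).reshape(-1, 2)
        self.b_r0 = np.array([t.r0 for t in b])
        self.b_k = np.array([t.k_b for t in b])
        a = topology.angles
        self.a_ijk = np.array([[t.i, t.j, t.k] for t in a], dtype=int).reshape(-1, 3)
        self.a_cos0 = np.array([math.cos(math.radians(t.theta0)) for t in a])
        self.a_k = np.array([t.k_theta for t in a])
        d = topology.dihedrals
        self.d_ijkl = np.array([[t.i, t.j, t.k, t.l] for t in d],
                               dtype=int).reshape(-1, 4)
        self.d_k = np.array([t.k_phi for t in d])
        self.d_n = np.array([t.n for t in d])
        self.d_ps = np.array([math.radians(t.phi_s) for t in d])

        self.wca = config.excluded_volume
        if self.wca:
            g = topology.molecule_graph
            close = {}
            for n in g.nodes:
                close[n] = set(nx.single_source_shortest_path_length(g, n, cutoff=2))
            real = [bd.id for bd in topology.beads if not bd.is_virtual]
            pairs = []
            for x in range(len(real)):
                for y in range(x + 1, len(real)):
                    i, j = real[x], real[y]
                    if j in close.get(i, ()):
                        continue
                    gi = topology.beads_by_id[i].rigid_group
                    gj = topology.beads_by_id[j].rigid_group
                    if gi is not None and gi == gj:
                        continue
                    pairs.append((i, j))
            self.p_ij = np.array(pairs, dtype=int).reshape(-1, 2)
            radii = {bd.id: bd.bead_type.vdw_radius for bd in topology.beads}
            self.p_sigma = np.array(
                [config.wca_sigma_scale * (radii[i] + radii[j])
                 for i, j in self.p_ij]).reshape(-1)
            self.p_eps = config.wca_epsilon
            # pairs of backbone (BB-named) beads may attract -- the surrogate
            # for protein-protein LJ cohesion that collapses bare chains
            bb = {bd.id for bd in topology.beads if bd.name == "BB"}
            self.p_attr = np.array(
                [config.backbone_attraction > 0 and i in bb and j in bb
                 for i, j in self.p_ij], dtype=bool)
            self.attr_eps = config.backbone_attraction

    def energy(self, x: np.ndarray) -> float:
        e = 0.0
        if len(self.b_ij):
            r = np.linalg.norm(x[self.b_ij[:, 0]] - x[self.b_ij[:, 1]], axis=1)
            e += float(np.sum(0.5 * self.b_k * (r - self.b_r0) ** 2))
        if len(self.a_ijk):
            v1 = x[self.a_ijk[:, 0]] - x[self.a_ijk[:, 1]]
            v2 = x[self.a_ijk[:, 2]] - x[self.a_ijk[:, 1]]
            c = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            c = np.clip(c, -1.0, 1.0)
            s2 = np.clip(1.0 - c * c, 1e-10, None)
            e += float(np.sum(0.5 * self.a_k * (c - self.a_cos0) ** 2 / s2))
        if len(self.d_ijkl):
            b0 = x[self.d_ijkl[:, 1]] - x[self.d_ijkl[:, 0]]
            b1 = x[self.d_ijkl[:, 2]] - x[self.d_ijkl[:, 1]]
            b2 = x[self.d_ijkl[:, 3]] - x[self.d_ijkl[:, 2]]
            n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
            m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1)[:, None])
            phi = np.arctan2(np.einsum("ij,ij->i", m1, n2),
                             np.einsum("ij,ij->i", n1, n2))
            e += float(np.sum(self.d_k * (1.0 + np.cos(self.d_n * phi - self.d_ps))))
        if self.wca and len(self.p_ij):
            d = np.linalg.norm(x[self.p_ij[:, 0]] - x[self.p_ij[:, 1]], axis=1)
            rep = ~self.p_attr
            cut = self.p_sigma * 2.0 ** (1.0 / 6.0)
            mask = rep & (d < cut)
            if mask.any():
                sr6 = (self.p_sigma[mask] / d[mask]) ** 6
                e += float(np.sum(4.0 * self.p_eps * (sr6 * sr6 - sr6) + self.p_eps))
            if self.p_attr.any():
                mask = self.p_attr & (d < 2.5 * self.p_sigma)
                if mask.any():
                    sr6 = (self.p_sigma[mask] / d[mask]) ** 6
                    e += float(np.sum(4.0 * self.attr_eps * (sr6 * sr6 - sr6)))
        return e


def mc_sample_molecule(
    topology: CGTopology, config: SamplerConfig | None = None
) -> MCResult:
    """Metropolis Monte Carlo over Cartesian bead positions.

    Moves: single-bead displacements, rigid-body moves of monosaccharide
    groups, and optional subtree pivots for chains.  Virtual sites are
    recomputed at the center of geometry of their group after every accepted
    move.  Deterministic for a fixed seed.
    """
    if config is None:
        config = SamplerConfig()
    rng = np.random.default_rng(config.seed)
    model = _EnergyModel(topology, config)
    x = topology.coordinates().copy()
    by_id = topology.beads_by_id

    free = [b.id for b in topology.beads
            if not b.is_virtual and b.rigid_group is None]
    groups = [sorted(m) for m in topology.rigid_groups.values()]
    if not free and not groups:
        raise ValueError("topology has no movable beads")
    # spanning tree for pivot moves
    pivot_edges: list[tuple[int, list[int]]] = []
    if config.pivot_prob > 0:
        g = topology.molecule_graph
        root = topology.n_term if topology.n_term is not None else topology.beads[0].id
        tree = nx.bfs_tree(g, root)
        for u, v in tree.edges:
            sub = list(nx.descendants(tree, v)) + [v]
            if 0 < len(sub) < len(topology.beads):
                pivot_edges.append((u, sub))

    def fix_virtuals(arr: np.ndarray) -> None:
        for gid, members in topology.rigid_groups.items():
            vs = [m for m in members if by_id[m].is_virtual]
            real = [m for m in members if not by_id[m].is_virtual]
            for v in vs:
                arr[v] = arr[real].mean(axis=0)

    fix_virtuals(x)
    e = model.energy(x)
    kT = KB * config.temperature
    n_accept = 0
    frames, energies = [], []
    stuck_probe = min(config.probe_window, config.n_steps)

    for step in range(config.n_steps):
        trial = x.copy()
        u = rng.random()
        if pivot_edges and u < config.pivot_prob:
            anchor, sub = pivot_edges[rng.integers(len(pivot_edges))]
            rot = _random_rotation(rng)
            trial[sub] = (trial[sub] - trial[anchor]) @ rot.T + trial[anchor]
        elif groups and (not free or u < config.pivot_prob + 0.3):
            members = groups[rng.integers(len(groups))]
            shift = rng.uniform(-config.step, config.step, 3)
            rot = _random_rotation(rng)
            center = trial[members].mean(axis=0)
            trial[members] = (trial[members] - center) @ rot.T + center + shift
        else:
            i = free[rng.integers(len(free))]
            trial[i] = trial[i] + rng.uniform(-config.step, config.step, 3)
        fix_virtuals(trial)
        e_new = model.energy(trial)
        if e_new <= e or rng.random() < math.exp(-(e_new - e) / kT):
            x, e = trial, e_new
            n_accept += 1
        if step + 1 == stuck_probe and n_accept == 0:
            raise StuckSamplerError(
                f"no accepted moves in {stuck_probe} steps "
                f"(energy {e:.3g} kJ/mol); reduce the step size"
            )
        if (step + 1) % config.sample_every == 0:
            frames.append(x.copy())
            energies.append(e)

    traj = TrajectoryFrameSet(np.array(frames).reshape(len(frames), -1, 3)
                              if frames else np.zeros((0, len(x), 3)))
    return MCResult(frames=traj, acceptance_rate=n_accept / config.n_steps,
                    n_steps=config.n_steps, energies=np.array(energies))


# ---------------------------------------------------------------------------
# Brush-chain surrogates for Flory-scaling demonstrations
# ---------------------------------------------------------------------------


def brush_chain(
    n_units: int,
    beads_per_unit: int = 8,
    glycosylated: bool = False,
    side_radius: float = 0.50,
    side_every: int = 1,
) -> CGTopology:
    """Backbone chain of ``n_units`` repeat units, optionally with bulky side
    beads along the backbone (a soft-repulsion surrogate for the mutual
    repulsion of densely grafted charged glycans)."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    n_bb = n_units * beads_per_unit
    bb_type = BeadType("P2", "R")
    side_type = BeadType("BRUSH", "R", vdw_radius=side_radius)
    beads: list[Bead] = []
    bonds: list[HarmonicBondTerm] = []
    angles: list[ReBAngleTerm] = []
    for i in range(n_bb):
        zig = 0.03 * (1 if i % 2 else -1)
        beads.append(Bead(id=len(beads), bead_type=bb_type,
                          position=np.array([0.35 * i, zig, 0.0]),
                          constituent_atoms=[f"bb{i}:X1", f"bb{i}:X2"],
                          residue_id=i + 1, name="BB"))
    for i in range(n_bb - 1):
        bonds.append(HarmonicBondTerm(i, i + 1, r0=0.35, k_b=4000.0))
    for i in range(n_bb - 2):
        angles.append(ReBAngleTerm(i, i + 1, i + 2, theta0=130.0, k_theta=25.0))
    if glycosylated:
        for i in range(0, n_bb, side_every):
            sid = len(beads)
            beads.append(Bead(id=sid, bead_type=side_type,
                              position=np.array([0.35 * i, 0.45, 0.0]),
                              constituent_atoms=[f"sc{i}:X1", f"sc{i}:X2"],
                              residue_id=i + 1, name="SC"))
            bonds.append(HarmonicBondTerm(i, sid, r0=0.45, k_b=4000.0))
    topo = CGTopology(beads=beads, bonds=bonds, angles=angles,
                      name=f"brush{n_units}" if glycosylated else f"bare{n_units}",
                      n_term=0, c_term=n_bb - 1, n_residues=n_bb)
    topo.residue_names = {i + 1: "CHN" for i in range(n_bb)}
    return topo


def flory_scaling_demo(
    units: tuple[int, ...] = (1, 2, 3, 4),
    beads_per_unit: int = 8,
    n_steps: int = 30_000,
    seed: int = 100,
    backbone_attraction: float = 5.0,
) -> dict:
    """Flory exponents of sampled bare vs brush chains (qualitative contrast).

    The bare backbone carries cohesive LJ self-attraction (it collapses);
    the brush chain adds bulky repulsive side beads standing in for charged
    glycans, which swell the chain.  Returns the two fitted exponents; the
    expected direction is v_glycosylated > v_bare.
    """
    from .analysis import fit_flory, radius_of_gyration

    out = {}
    for label, glyco in (("bare", False), ("glycosylated", True)):
        rgs, mws = [], []
        for k, u in enumerate(units):
            topo = brush_chain(u, beads_per_unit=beads_per_unit,
                               glycosylated=glyco)
            cfg = SamplerConfig(
                n_steps=n_steps, sample_every=100, step=0.08,
                seed=seed + 13 * k + (7 if glyco else 0),
                excluded_volume=True, pivot_prob=0.4,
                backbone_attraction=backbone_attraction,
            )
            res = mc_sample_molecule(topo, cfg)
            frames = res.frames.positions[res.frames.n_frames // 3:]
            masses = topo.masses()
            rgs.append(float(np.mean([radius_of_gyration(f, masses)
                                      for f in frames])))
            mws.append(topo.total_mass())
        fit = fit_flory(np.array(rgs), np.array(mws))
        out[label] = {"v": fit.v, "rg": rgs, "mw": mws}
    return out
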