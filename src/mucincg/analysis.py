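"""Structural validation metrics for CG (or pseudo-CG) trajectories.

Radius of gyration, end-to-end distance, solvent-accessible surface area
(SASA), radial distribution functions, RMSD against a reference, the Flory
power-law fit Rg = R0 * Mw^v, and the protein-protein Lennard-Jones
downscaling used to loosen overly sticky MARTINI self-interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CGTopology, NonbondedParams, SIZE_CLASS_RADII
from .mapper import TrajectoryFrameSet

__all__ = [
    "SasaConfig",
    "StructuralMetrics",
    "FloryFit",
    "RdfProfile",
    "SelectionError",
    "radius_of_gyration",
    "end_to_end_distance",
    "sasa",
    "rdf",
    "rmsd_pseudo_cg",
    "fit_flory",
    "downscale_protein_lj",
    "structural_metrics",
]

#: Virtual beads (mass below this, in Da) are excluded from mass-weighted metrics.
MASS_EPS = 1e-6


class SelectionError(ValueError):
    """An empty or undefined particle selection."""


@dataclass(frozen=True)
class SasaConfig:
    """SASA settings: probe radius and per-size-class bead radii (nm)."""

    probe_radius: float = 0.191
    radii: dict = field(default_factory=lambda: dict(SIZE_CLASS_RADII))
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be >= 0")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("bead radii must be positive")


@dataclass
class StructuralMetrics:
    """Per-frame Rg / Ree / SASA with summary statistics."""

    rg: np.ndarray
    ree: np.ndarray | None = None
    sasa: np.ndarray | None = None

    def summary(self) -> dict:
        out = {}
        for key in ("rg", "ree", "sasa"):
            v = getattr(self, key)
            if v is not None:
                out[key] = {"mean": float(np.mean(v)), "sd": float(np.std(v))}
        return out


@dataclass
class FloryFit:
    """Power-law fit Rg = R0 * Mw^v on log-log axes."""

    R0: float
    v: float
    v_stderr: float
    residuals: np.ndarray

    def predict(self, mw: np.ndarray) -> np.ndarray:
        return self.R0 * np.asarray(mw, dtype=float) ** self.v


@dataclass
class RdfProfile:
    """g(r) on bin centers with its normalization metadata."""

    bin_centers: np.ndarray
    g: np.ndarray
    density_b: float
    n_a: int
    box_volume: float
    counts: np.ndarray


def radius_of_gyration(positions: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass (nm).

    Near-massless virtual sites are excluded.
    """
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    keep = masses > MASS_EPS
    if not keep.any():
        raise SelectionError("no massive particles selected")
    p, m = positions[keep], masses[keep]
    com = np.average(p, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((p - com) ** 2, axis=1), weights=m)))


def end_to_end_distance(backbone_first: np.ndarray, backbone_last: np.ndarray) -> float:
    """Euclidean distance between the two terminal backbone beads (nm)."""
    if backbone_first is None or backbone_last is None:
        raise SelectionError("backbone termini are undefined")
    return float(np.linalg.norm(np.asarray(backbone_last) - np.asarray(backbone_first)))


# ---------------------------------------------------------------------------
# SASA (sphere-point sampling over the union of probe-extended spheres)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    topology: CGTopology,
    coords: np.ndarray,
    config: SasaConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Total and per-bead solvent-accessible surface area (nm^2).

    Test points are distributed on each bead's probe-extended sphere; points
    inside any neighbour's extended sphere are occluded.  Virtual sites are
    excluded.
    """
    if config is None:
        config = SasaConfig()
    coords = np.asarray(coords, dtype=float)
    keep = [i for i, b in enumerate(topology.beads) if not b.is_virtual]
    pos = coords[keep]
    radii = np.array(
        [config.radii[topology.beads[i].bead_type.size_class] for i in keep]
    )
    ext = radii + config.probe_radius
    sphere = _fibonacci_sphere(config.n_sphere_points)
    per_bead = np.zeros(len(topology.beads))
    for a in range(len(keep)):
        pts = pos[a] + ext[a] * sphere
        d = np.linalg.norm(pos - pos[a], axis=1)
        nbrs = np.where((d < ext + ext[a]) & (np.arange(len(keep)) != a))[0]
        exposed = np.ones(len(pts), dtype=bool)
        for b in nbrs:
            exposed &= np.sum((pts - pos[b]) ** 2, axis=1) > ext[b] ** 2
        per_bead[keep[a]] = 4.0 * np.pi * ext[a] ** 2 * exposed.mean()
    return float(per_bead.sum()), per_bead


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------


def rdf(
    group_a_coords: np.ndarray,
    group_b_coords: np.ndarray,
    box: np.ndarray | float,
    bins: int = 100,
    r_max: float | None = None,
) -> RdfProfile:
    """Radial distribution function under the minimum-image convention.

    ``group_b`` provides the surrounding density; identical arrays are
    treated as one self-group (self-pairs excluded).  The histogram is
    normalized by ideal-gas shell counts.
    """
    a = np.asarray(group_a_coords, dtype=float)
    b = np.asarray(group_b_coords, dtype=float)
    if a.size == 0 or b.size == 0:
        raise SelectionError("empty particle group for RDF")
    box = np.asarray(box, dtype=float) * np.ones(3)
    if r_max is None:
        r_max = float(box.min()) / 2.0
    if r_max > box.min() / 2.0 + 1e-12:
        raise ValueError("r_max must not exceed half the smallest box edge")
    same = a.shape == b.shape and np.array_equal(a, b)
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt(np.sum(d * d, axis=2))
    if same:
        iu = np.triu_indices(len(a), k=1)
        r = r[iu]
        n_pairs_per_a = len(b) - 1
    else:
        r = r.ravel()
        n_pairs_per_a = len(b)
    edges = np.linspace(0.0, r_max, bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    if same:
        counts = counts * 2  # each unordered pair contributes to both centers
    vol = float(np.prod(box))
    rho_b = n_pairs_per_a / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = rho_b * shell * len(a)
    g = np.divide(counts, ideal, out=np.zeros_like(ideal), where=ideal > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfProfile(bin_centers=centers, g=g, density_b=rho_b, n_a=len(a),
                      box_volume=vol, counts=counts)


def glycan_rdf(
    traj: TrajectoryFrameSet,
    topology: CGTopology,
    box: np.ndarray | float,
    bins: int = 60,
    r_max: float | None = None,
    level: str = "glycan",
) -> RdfProfile:
    """Glycan-glycan RDF averaged over frames.

    ``level='glycan'`` uses glycan centers of geometry (default);
    ``level='bead'`` uses all glycan bead positions.
    """
    gids = sorted(set(topology.glycan_of_bead.values()))
    if not gids:
        raise SelectionError("topology has no glycans")
    members = {g: [i for i, gg in topology.glycan_of_bead.items() if gg == g]
               for g in gids}
    profiles = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        if level == "glycan":
            pts = np.array([pos[members[g]].mean(axis=0) for g in gids])
        else:
            pts = pos[[i for g in gids for i in members[g]]]
        profiles.append(rdf(pts, pts, box, bins=bins, r_max=r_max))
    g = np.mean([p.g for p in profiles], axis=0)
    counts = np.sum([p.counts for p in profiles], axis=0)
    p0 = profiles[0]
    return RdfProfile(p0.bin_centers, g, p0.density_b, p0.n_a, p0.box_volume, counts)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotation matrix least-squares-aligning centered mobile onto ref."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rmsd_pseudo_cg(
    traj: TrajectoryFrameSet, ref_coords: np.ndarray, superpose: bool = True
) -> np.ndarray:
    """Per-frame RMSD (nm) against a reference, with optional rigid fit."""
    ref = np.asarray(ref_coords, dtype=float)
    if traj.positions.shape[1:] != ref.shape:
        raise ValueError(
            f"trajectory frames {traj.positions.shape[1:]} do not match the "
            f"reference {ref.shape}"
        )
    out = np.empty(traj.n_frames)
    ref_c = ref - ref.mean(axis=0)
    for f in range(traj.n_frames):
        x = traj.positions[f]
        if superpose:
            xc = x - x.mean(axis=0)
            rot = _kabsch(xc, ref_c)
            diff = xc @ rot.T - ref_c
        else:
            diff = x - ref
        out[f] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Flory scaling
# ---------------------------------------------------------------------------


def fit_flory(rg_values: np.ndarray, molecular_weights: np.ndarray) -> FloryFit:
    """Ordinary least squares of ln Rg on ln Mw: v = slope, R0 = exp(intercept)."""
    rg = np.asarray(rg_values, dtype=float)
    mw = np.asarray(molecular_weights, dtype=float)
    if rg.size != mw.size or rg.size < 2:
        raise ValueError("need >= 2 matching (Rg, Mw) points")
    if np.any(rg <= 0) or np.any(mw <= 0):
        raise ValueError("Rg and Mw must be positive")
    x, y = np.log(mw), np.log(rg)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    v = float(np.sum((x - xm) * (y - ym)) / sxx)
    b0 = ym - v * xm
    resid = y - (b0 + v * x)
    if n > 2:
        stderr = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        stderr = float("nan")
    return FloryFit(R0=float(np.exp(b0)), v=v, v_stderr=stderr, residuals=resid)


# ---------------------------------------------------------------------------
# LJ downscaling
# ---------------------------------------------------------------------------


def downscale_protein_lj(
    params: NonbondedParams,
    factor: float,
    scaled_groups: tuple[str, ...] = ("protein", "glycan"),
) -> NonbondedParams:
    """Scale epsilon by ``factor`` for pairs internal to the scaled groups.

    With the default grouping this rescales protein-protein interactions
    (backbone, side chains and attached glycans) while leaving any pair
    involving water or ions untouched; sigma is never changed.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    out = params.copy()
    for (a, b), (sigma, eps) in params.pairs():
        if params.groups.get(a) in scaled_groups and params.groups.get(b) in scaled_groups:
            out.set(a, b, sigma, eps * factor)
    return out


# ---------------------------------------------------------------------------
# Convenience: per-frame metrics over a trajectory
# ---------------------------------------------------------------------------


def structural_metrics(
    traj: TrajectoryFrameSet,
    topology: CGTopology,
    compute_sasa: bool = False,
    sasa_config: SasaConfig | None = None,
) -> StructuralMetrics:
    masses = topology.masses()
    rg = np.array([radius_of_gyration(traj.positions[f], masses)
                   for f in range(traj.n_frames)])
    ree = None
    if topology.n_term is not None and topology.c_term is not None:
        ree = np.array([
            end_to_end_distance(traj.positions[f, topology.n_term],
                                traj.positions[f, topology.c_term])
            for f in range(traj.n_frames)
        ])
    areas = None
    if compute_sasa:
        areas = np.array([sasa(topology, traj.positions[f], sasa_config)[0]
                          for f in range(traj.n_frames)])
    return StructuralMetrics(rg=rg, ree=ree, sasa=areas)
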