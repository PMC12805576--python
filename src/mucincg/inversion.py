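"""Modified Boltzmann inversion of bonded distributions.

Bonded degrees of freedom measured over a (pseudo-)CG trajectory are turned
into force-field parameters:

* harmonic bonds by Gaussian moment matching, ``r0 = <r>`` and
  ``k_b = kB*T / Var(r)``;
* restricted-bending (ReB) angles by locating the mode of the
  Jacobian-corrected potential of mean force (PMF) and matching the variance
  of the exact ReB Boltzmann density ``p(theta) ~ sin(theta) exp(-V/kBT)``;
* periodic dihedrals by least squares of ``k(1 + cos(n phi - phi_s))``
  against the PMF ``-kB*T ln p(phi)`` over candidate multiplicities.

Degrees of freedom generated by rigid monosaccharide groups never appear
here: the mapper excludes their bonded terms from the topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import (
    KB,
    DEFAULT_TEMPERATURE,
    CGTopology,
    HarmonicBondTerm,
    PeriodicDihedralTerm,
    ReBAngleTerm,
    SingularityError,
)
from .mapper import TrajectoryFrameSet

__all__ = [
    "BondedDistribution",
    "FitResult",
    "InsufficientDataError",
    "RigidDegreeOfFreedomError",
    "TooRigidDihedralError",
    "measure_distributions",
    "fit_harmonic_bond",
    "fit_reb_angle",
    "fit_periodic_dihedral",
    "compare_distributions",
    "fit_all",
]

#: Default histogram bin widths: bonds (nm), angles (deg), dihedrals (deg).
BIN_WIDTHS = {"bond": 0.001, "angle": 1.0, "dihedral": 5.0}


class InsufficientDataError(ValueError):
    """Too few frames/samples to measure or fit a distribution."""


class RigidDegreeOfFreedomError(ValueError):
    """Zero-variance samples: the degree of freedom should be constrained."""


class TooRigidDihedralError(ValueError):
    """Dihedral samples leave most of the angular range empty."""


@dataclass
class BondedDistribution:
    """Samples of one bonded degree of freedom (nm for bonds, deg otherwise)."""

    kind: str                     # "bond" | "angle" | "dihedral"
    indices: tuple[int, ...]
    samples: np.ndarray
    bin_width: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.bin_width is None:
            self.bin_width = BIN_WIDTHS[self.kind]

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def variance(self) -> float:
        return float(self.samples.var())

    @property
    def n(self) -> int:
        return self.samples.size

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts) on a grid aligned to multiples of bin_width."""
        w = self.bin_width
        if self.kind == "dihedral":
            edges = np.arange(-180.0, 180.0 + w / 2, w)
        elif self.kind == "angle":
            edges = np.arange(0.0, 180.0 + w / 2, w)
        else:
            lo = math.floor(self.samples.min() / w) * w
            hi = math.ceil(self.samples.max() / w) * w + w
            edges = np.arange(lo, hi + w / 2, w)
        counts, edges = np.histogram(self.samples, bins=edges)
        return edges, counts


@dataclass
class FitResult:
    """A fitted bonded term with its fit diagnostics."""

    term: HarmonicBondTerm | ReBAngleTerm | PeriodicDihedralTerm
    gof: float                    # RMS residual of the PMF fit (kJ/mol)
    n_samples: int
    warnings: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def _bond_lengths(pos: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.linalg.norm(pos[:, i] - pos[:, j], axis=1)


def _angles_deg(pos: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    v1 = pos[:, i] - pos[:, j]
    v2 = pos[:, k] - pos[:, j]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedrals_deg(pos: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    b0 = pos[:, j] - pos[:, i]
    b1 = pos[:, k] - pos[:, j]
    b2 = pos[:, l] - pos[:, k]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.degrees(np.arctan2(y, x))
    phi[phi <= -180.0] += 360.0
    return phi


def measure_distributions(
    cg_traj: TrajectoryFrameSet, topology: CGTopology
) -> list[BondedDistribution]:
    """One distribution per bonded term of the topology.

    Bond lengths in nm; angles and dihedrals in degrees, dihedrals wrapped to
    (-180, 180].  Collinear angle samples (180 deg) are flagged since the
    restricted-bending potential is singular there.
    """
    if cg_traj.n_sites != len(topology.beads):
        raise ValueError(
            f"trajectory has {cg_traj.n_sites} sites, topology has "
            f"{len(topology.beads)} beads"
        )
    if cg_traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames to measure distributions")
    pos = cg_traj.positions
    out: list[BondedDistribution] = []
    for t in topology.bonds:
        out.append(BondedDistribution("bond", (t.i, t.j), _bond_lengths(pos, t.i, t.j)))
    for t in topology.angles:
        samples = _angles_deg(pos, t.i, t.j, t.k)
        d = BondedDistribution("angle", (t.i, t.j, t.k), samples)
        if np.any(samples >= 180.0 - 1e-9):
            d.warnings.append("collinear samples at 180 deg (ReB is singular there)")
        out.append(d)
    for t in topology.dihedrals:
        out.append(
            BondedDistribution(
                "dihedral", (t.i, t.j, t.k, t.l), _dihedrals_deg(pos, t.i, t.j, t.k, t.l)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_harmonic_bond(
    dist: BondedDistribution, T: float = DEFAULT_TEMPERATURE
) -> FitResult:
    """Gaussian Boltzmann inversion: r0 = mean, k_b = kB*T / variance."""
    warnings = list(dist.warnings)
    if dist.variance <= 0.0:
        raise RigidDegreeOfFreedomError(
            "zero-variance bond samples; constrain this degree of freedom instead"
        )
    if dist.n < 100:
        warnings.append(f"only {dist.n} samples (< 100); k_b estimate is noisy")
    r0 = dist.mean
    k_b = KB * T / dist.variance
    i, j = (dist.indices + (0, 1))[:2]
    term = HarmonicBondTerm(i=i, j=j, r0=r0, k_b=k_b)
    # residual of the fitted PMF against the empirical PMF
    edges, counts = dist.histogram()
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    pmf = -KB * T * np.log(counts[mask] / counts.sum() / dist.bin_width)
    model = 0.5 * k_b * (centers[mask] - r0) ** 2
    gof = float(np.sqrt(np.mean(((pmf - pmf.min()) - (model - model.min())) ** 2)))
    return FitResult(term=term, gof=gof, n_samples=dist.n, warnings=warnings)


def _reb_density(theta_deg: np.ndarray, theta0: float, k_theta: float,
                 T: float) -> np.ndarray:
    """Unnormalized ReB Boltzmann density with the sin(theta) Jacobian."""
    t = np.radians(theta_deg)
    s = np.sin(t)
    v = 0.5 * k_theta * (np.cos(t) - math.cos(math.radians(theta0))) ** 2 / s**2
    return s * np.exp(-(v - v.min()) / (KB * T))


def _reb_model_variance(theta0: float, k_theta: float, T: float) -> float:
    grid = np.arange(0.05, 180.0, 0.05)
    p = _reb_density(grid, theta0, k_theta, T)
    p /= p.sum()
    mu = float(np.sum(grid * p))
    return float(np.sum((grid - mu) ** 2 * p))


def fit_reb_angle(dist: BondedDistribution, T: float = DEFAULT_TEMPERATURE) -> FitResult:
    """Fit a restricted-bending angle term.

    theta0 is the mode of the smoothed, Jacobian-corrected PMF; k_theta is
    found by a 1-D root search so that the variance of the exact ReB
    Boltzmann density matches the sample variance.
    """
    s = dist.samples
    if np.any(s >= 180.0) or np.any(s <= 0.0):
        raise SingularityError("angle samples at or beyond 0/180 deg")
    if dist.variance <= 0.0:
        raise RigidDegreeOfFreedomError(
            "zero-variance angle samples; constrain this degree of freedom instead"
        )
    warnings = list(dist.warnings)
    if dist.n < 100:
        warnings.append(f"only {dist.n} samples (< 100); fit is noisy")

    edges, counts = dist.histogram()
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / counts.sum() / dist.bin_width
    mask = counts > 0
    # remove the sin(theta) Jacobian, then smooth the PMF before mode finding
    pmf = np.full_like(centers, np.nan)
    pmf[mask] = -KB * T * np.log(
        density[mask] / np.sin(np.radians(centers[mask]))
    )
    sm = _moving_average_nan(pmf, 3)
    theta0 = float(centers[np.nanargmin(sm)])
    # refine the mode: the PMF is locally quadratic, so a parabola through the
    # basin pins the vertex far better than the lowest 1-degree bin
    win = np.isfinite(pmf) & (np.abs(centers - theta0) <= 12.0)
    if win.sum() >= 5:
        a2, a1, _ = np.polyfit(centers[win], pmf[win], 2)
        if a2 > 0:
            vertex = -a1 / (2.0 * a2)
            if abs(vertex - theta0) <= 12.0 and 0.0 < vertex < 180.0:
                theta0 = float(vertex)

    target = dist.variance

    def f(log10k: float) -> float:
        return _reb_model_variance(theta0, 10.0**log10k, T) - target

    lo, hi = -2.0, 6.0
    if f(lo) < 0:      # even a very soft angle is narrower than the samples
        k_theta = 10.0**lo
        warnings.append("sample variance exceeds the softest ReB model variance")
    elif f(hi) > 0:
        k_theta = 10.0**hi
        warnings.append("sample variance below the stiffest ReB model variance")
    else:
        k_theta = 10.0 ** brentq(f, lo, hi, xtol=1e-4)

    term = ReBAngleTerm(*(dist.indices + (0, 1, 2))[:3], theta0=theta0,
                        k_theta=float(k_theta))
    model = np.array([term.energy(c) for c in centers[mask]])
    emp = pmf[mask]
    gof = float(np.sqrt(np.mean(((emp - np.nanmin(emp)) - (model - model.min())) ** 2)))
    return FitResult(term=term, gof=gof, n_samples=dist.n, warnings=warnings)


def _moving_average_nan(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average that ignores NaNs."""
    out = np.full_like(x, np.nan)
    h = w // 2
    for i in range(len(x)):
        seg = x[max(0, i - h): i + h + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def fit_periodic_dihedral(
    dist: BondedDistribution,
    T: float = DEFAULT_TEMPERATURE,
    multiplicities: tuple[int, ...] = (1, 2, 3),
    smooth: bool = True,
) -> FitResult:
    """Least-squares PMF fit of k_phi (1 + cos(n phi - phi_s)).

    The PMF is -kB*T ln(normalized histogram), offset to zero minimum.  The
    candidate multiplicity with the lowest residual wins.  The number of PMF
    minima (modes of the sample density) is reported as a multimodality
    diagnostic.
    """
    warnings = list(dist.warnings)
    if dist.n < 1000:
        warnings.append(f"only {dist.n} samples (< 1000); PMF is noisy")
    edges, counts = dist.histogram()
    centers = 0.5 * (edges[:-1] + edges[1:])
    empty_frac = np.mean(counts == 0)
    if empty_frac > 0.5:
        raise TooRigidDihedralError(
            f"{empty_frac:.0%} of the dihedral range has no samples; "
            "treat this torsion as rigid/constrained instead"
        )
    mask = counts > 0
    pmf = -KB * T * np.log(counts[mask] / counts.sum() / dist.bin_width)
    pmf -= pmf.min()
    phi = np.radians(centers[mask])

    best = None
    for n in multiplicities:
        design = np.column_stack([np.ones_like(phi), np.cos(n * phi), np.sin(n * phi)])
        coef, *_ = np.linalg.lstsq(design, pmf, rcond=None)
        resid = float(np.sqrt(np.mean((design @ coef - pmf) ** 2)))
        if best is None or resid < best[0]:
            best = (resid, n, coef)
    resid, n, (c0, a, b) = best
    k_phi = float(np.hypot(a, b))
    phi_s = float(np.degrees(np.arctan2(b, a)))

    # multimodality: count modes of the (circularly smoothed) sample density
    dens = counts.astype(float)
    if smooth:
        for _ in range(3):
            dens = (np.roll(dens, 1) + dens + np.roll(dens, -1)) / 3.0
    n_modes = _count_circular_modes(dens)

    term = PeriodicDihedralTerm(*(dist.indices + (0, 1, 2, 3))[:4],
                                k_phi=k_phi, n=int(n), phi_s=phi_s)
    return FitResult(
        term=term, gof=resid, n_samples=dist.n, warnings=warnings,
        diagnostics={"n_pmf_minima": n_modes, "empty_bin_fraction": float(empty_frac)},
    )


def _count_circular_modes(dens: np.ndarray, rel_threshold: float = 0.1,
                          min_prominence: float = 0.2) -> int:
    """Local maxima of a circular histogram, filtered by prominence.

    A candidate peak only counts if the density drops by at least
    ``min_prominence * max`` between it and the neighbouring candidates.
    """
    if dens.max() <= 0:
        return 0
    thr = rel_threshold * dens.max()
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    cand = np.where((dens > left) & (dens >= right) & (dens > thr))[0]
    if len(cand) <= 1:
        return max(len(cand), 1)
    # merge candidates not separated by a deep enough valley
    n = len(dens)
    kept = []
    for idx in sorted(cand, key=lambda i: -dens[i]):
        ok = True
        for j in kept:
            lo, hi = sorted((idx, j))
            inner = dens[lo:hi + 1]
            outer = np.concatenate([dens[hi:], dens[:lo + 1]])
            # the easiest route between two circular peaks crosses the
            # higher of the two arc minima (the connecting saddle)
            valley = max(inner.min(), outer.min())
            if min(dens[idx], dens[j]) - valley < min_prominence * dens.max():
                ok = False
                break
        if ok:
            kept.append(idx)
    return max(len(kept), 1)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------


def compare_distributions(ref: BondedDistribution, test: BondedDistribution) -> dict:
    """Absolute percentage deviation of means + histogram overlap coefficient."""
    if ref.kind != test.kind:
        raise ValueError(f"cannot compare {ref.kind} with {test.kind}")
    dev = abs(test.mean - ref.mean) / abs(ref.mean) * 100.0
    w = min(ref.bin_width, test.bin_width)
    lo = min(ref.samples.min(), test.samples.min())
    hi = max(ref.samples.max(), test.samples.max())
    edges = np.arange(math.floor(lo / w) * w, math.ceil(hi / w) * w + 1.5 * w, w)
    p, _ = np.histogram(ref.samples, bins=edges)
    q, _ = np.histogram(test.samples, bins=edges)
    overlap = float(np.minimum(p / p.sum(), q / q.sum()).sum())
    return {"deviation_percent": float(dev), "overlap": overlap}


def fit_all(
    distributions: list[BondedDistribution], T: float = DEFAULT_TEMPERATURE
) -> list[FitResult]:
    """Fit every distribution with the fitter matching its kind."""
    fitters = {
        "bond": fit_harmonic_bond,
        "angle": fit_reb_angle,
        "dihedral": fit_periodic_dihedral,
    }
    return [fitters[d.kind](d, T) for d in distributions]
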