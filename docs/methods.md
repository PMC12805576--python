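# Methods

## Model and conventions

`mucincg` builds MARTINI 3 coarse-grained models of O-glycosylated
peptides. Beads group 2 (tiny, T), 3 (small, S) or 4 (regular, R) heavy
atoms and sit at the unweighted center of geometry of their constituent
atoms. Size class fixes the van der Waals radius (0.191 / 0.230 / 0.264 nm)
and mass (36 / 54 / 72 Da); both are overridable per bead type through the
YAML tables. Internal units are nm, kJ/mol, Da, and degrees at API
boundaries (radians internally); `k_B = 0.0083145 kJ mol⁻¹ K⁻¹` and the
default temperature is 300 K.

Three bonded forms are supported:

* harmonic bond, `V = ½ k_b (r − r0)²` (the GROMACS convention; the LAMMPS
  writer converts to its `V = K x²` dialect, `K = k_b/2`, kcal/Å units);
* restricted-bending (ReB) angle,
  `V = ½ k_θ (cos θ − cos θ0)² / sin² θ`, which diverges at 0° and 180° and
  thereby keeps CG triples away from the collinear geometries where
  dihedral forces blow up;
* periodic dihedral, `V = k_φ (1 + cos(nφ − φ_s))`, IUPAC torsion sign,
  wrapped to (−180°, 180°].

Monosaccharides are rigid bodies: each sugar's three ring beads form a
rigid group with no internal bonded terms (their distributions in real
simulations are delta-like), and a TC4 virtual site of negligible mass
(10⁻¹⁰ Da internally) rides at the ring's center of geometry.

### O-glycan mapping rules

The glycosidic oxygen bridging two sugars is assigned to the glycosyl
*acceptor* (the sugar contributing the hydroxyl). The donor loses its
anomeric hydroxyl on bond formation, so its anomeric bead shrinks by one
atom: for N-acetylhexosamines (GalNAc, GlcNAc) the SN6 bead becomes a TC5
bead holding the –CH–CH– pair (the raised polarity reflects the flanking
amide and glycosidic oxygen); for other sugars the package retypes to a
generic tiny N-bead (TN6), a package convention since the shrunken bead
must change size class. Thr–glycan and Ser–glycan linkage beads are typed
SN4ar and TN4ar respectively; sulfate groups map to a Q4n bead with charge
−1, and sialic-acid carboxylates to an SQ5n bead with charge −1. Histidine
is mapped neutral (its imidazole pKa ≈ 6 sits below physiological pH).

## Packaged tables and the Mini2 construct

The per-sugar bead tables and the Mini2 MUC5B composition are **synthetic
stand-ins**: they keep the published architecture (three ring beads plus
side beads, the bead chemotypes above, the strict 2/3/4 atoms-per-bead
rule) but use a reduced heavy-atom complement and a designed 30-residue
PTS sequence (`TTSPTGTSTPTSTGTTSPTGTSTPTGSTHG`, one neutral His near the
C-terminus, no Ala — the single-atom Ala side bead would break the
atoms-per-bead rule). The 18 glycans (13 Thr-linked, 5 Ser-linked) are
11 sialyl-T trees (−1 each), 2 sulfo-T trees (−1 each) and 5 Tn stubs,
giving the published net charge of −13 e. Every table is a YAML file under
`mucincg/data/` and user-replaceable; mapping real chemistries requires
supplying measured templates.

## Modified Boltzmann inversion

"Inversion" here means three kind-specific fits of the potential of mean
force (PMF):

* **Bonds** — Gaussian moment matching: `r0 = ⟨r⟩`, `k_b = k_BT / Var(r)`.
  The identity `k_b · Var = k_BT` holds by construction.
* **Angles** — the sin θ Jacobian is removed from the 1°-binned histogram,
  the PMF is smoothed with a 3-bin moving average, and θ0 is the vertex of
  a parabola fitted through the PMF basin (±12°) around the lowest bin —
  the parabola step pins the flat minimum of soft angles far better than
  the raw argmin. k_θ is then found by a Brent root search (on log₁₀ k over
  [10⁻², 10⁶]) matching the variance of the exact ReB Boltzmann density
  `p(θ) ∝ sin θ · e^(−V/k_BT)` to the sample variance.
* **Dihedrals** — the PMF `−k_BT ln p(φ)` on 5° bins, offset to zero
  minimum, is fitted by linear least squares to
  `c + A cos nφ + B sin nφ` for each candidate multiplicity n ∈ {1, 2, 3};
  the best-residual n wins, with `k_φ = √(A² + B²)` and
  `φ_s = atan2(B, A)`. A multimodality diagnostic counts
  prominence-filtered modes of the circularly smoothed sample density
  (a mode needs a connecting saddle at least 20% of the peak below it);
  multimodal torsions that a single term cannot represent are reported,
  not refitted with a series.

Degrees of freedom inside rigid groups never reach the fitter: the mapper
excludes their terms from the topology. Zero-variance samples raise a
rigid-degree-of-freedom error (constrain instead), samples at 180° a
singularity error, and dihedrals with > 50% empty bins a too-rigid error.

## Solvation arithmetic

One W bead represents four water molecules. Water beads fill
`V_box − V_solute` to 1 g/cm³ (molar mass 18.015 g/mol; count floored).
Background NaCl pairs are computed **on the represented water volume** —
`pairs = round_half_even(c · 4 n_W · M_w / (ρ · 1000))` — not the box
volume; this convention reproduces the reference composition of 171 pairs
for 15,860 W beads at 150 mM (the box-volume convention gives ~176).
Neutralizing cations (or anions) are added on top of the background so
every plan is electroneutral by construction. Molecular volume is the
voxelized union of bead vdW spheres (0.02 nm voxels, overlaps counted
once); packing is random insertion with a cell list enforcing a 0.4 nm
minimum distance (10⁴ attempts per particle before a density error).

## File export

GROMACS files use nm/kJ and 1-based indices; harmonic bonds keep `k_b`
unchanged (GROMACS shares the ½k convention), ReB angles use angle
function 10, rigid rings are emitted as pairwise constraints plus
commented rigid-group metadata, and virtual sites as `virtual_sitesn`
(function 1, center of geometry). LAMMPS data files (full style, real
units) convert to Å/kcal, write `K = k_b/2/4.184/100` for bonds, export
ReB angles as tabulated potentials (721 points, 0.25° spacing, singular
endpoints clamped to 0.25°), and approximate the dihedral phase with the
integer degrees the charmm style requires — the exact value travels in a
comment that the paired reader prefers. Both writers quantize numeric
fields to their printed precision, so write → read → write is byte-stable;
constraint lengths are computed from the 0.001-nm-rounded coordinates the
`.gro` file stores for the same reason.

## Analysis metrics

Rg is mass-weighted (virtual sites excluded by a 10⁻⁶ Da threshold; a
geometric variant is available by passing unit masses). SASA uses
Shrake–Rupley-style sphere-point sampling with 960 Fibonacci points per
bead over probe-extended spheres (probe 0.191 nm) — the same quantity as
the double-cubic-lattice method, chosen because the single-sphere case is
analytic and the estimator is easy to cross-check against hit-or-miss
Monte-Carlo surface integration. RDFs use the minimum-image convention in
cubic boxes, normalized by ideal-gas shell counts; glycan–glycan RDFs
default to glycan centers of geometry with a bead-level mode available.
RMSD optionally superposes by Kabsch. The Flory fit is ordinary least
squares of ln Rg on ln Mw (v = slope, R0 = exp(intercept), with the OLS
standard error of the slope). LJ downscaling multiplies ε by the given
factor for pairs internal to the scaled groups (protein + glycans by
default), leaving σ and all water/ion pairs untouched; composition
`f₁∘f₂ = f₁·f₂` holds exactly.

## Synthetic data: what it emulates and what it does not

`generate_synthetic_trajectory` samples every bonded degree of freedom
from its exact target density — bonds from `N(r0, k_BT/k_b)` (the same
Gaussian convention the bond fitter inverts), angles from
`sin θ · e^(−V_ReB/k_BT)` by inverse-CDF on a 0.05° grid, dihedrals from
`e^(−V/k_BT)` — and rebuilds Cartesian frames by vectorized
natural-extension (NeRF) placement over a spanning tree of the bead graph,
with rigid groups reproduced at frozen internal geometry and random
orientation. Cycles outside rigid groups are rejected (no spanning set of
internal coordinates). These trajectories have *independent* internal
coordinates: they are ideal for round-trip tests of the inversion but
carry no excluded volume, no solvent, and no correlations between terms.

`mc_sample_molecule` is a desk-scale Metropolis sampler over Cartesian
bead positions (single-bead moves, rigid-body ring moves, optional subtree
pivots) targeting the bonded energy plus an optional WCA-style soft
repulsion. Because it samples in Cartesian space, bond-length marginals
carry the r² Jacobian absent from the internal-coordinate generator — the
tests compare against the r²-weighted density. Electrostatics are replaced
by a soft-repulsion surrogate; the sampler is not an MD engine and is not
meant to reproduce explicit-solvent observables.

The brush-chain scaling demo contrasts a bare backbone with cohesive LJ
self-attraction (5 kJ/mol between backbone beads — it collapses toward the
globule regime, ν ≈ 0.4) against the same backbone carrying bulky
repulsive side beads (radius 0.5 nm, one per backbone bead — a surrogate
for densely grafted charged glycans that swells the chain, ν ≈ 0.6–0.8).
Chains of 1–4 repeat units of 8 backbone beads are sampled for 3×10⁴ MC
steps each; these sizes keep the demonstration to tens of seconds on one
CPU while the direction of the contrast is robust across seeds. The
absolute exponents from this surrogate are not comparable to
explicit-solvent simulation or experiment — only the direction
(glycosylated > bare) is the claim, mirroring the structural collapse of
deglycosylated mucins.

## Numerical choices and limitations

* Histogram bins: 0.001 nm (bonds), 1° (angles), 5° (dihedrals);
  configurable per distribution.
* ReB evaluation clamps sin²θ at 10⁻¹⁰ in vectorized energy sums; the
  scalar API raises on exact 0°/180° instead.
* Angle-fit bracket: if the sample variance lies outside the softest or
  stiffest model variance the boundary value is returned with a warning.
* `build_repeats` joins copies with a single backbone harmonic bond
  (junction angles/dihedrals are not synthesized); mass, charge, residue
  and glycan counts scale exactly n-fold.
* Readers accept PDB/GRO via MDAnalysis (Å → nm on read); structures
  without bond records fall back to template-declared connectivity.
* The packaged LJ table is a bookkeeping table (class-based σ, one generic
  ε) sufficient for rescaling and export plumbing — engine-grade
  interaction matrices must be supplied by the user.
* Passing the synthetic-data tests shows the estimators are correct and
  self-consistent; it does not validate the packaged templates against
  real atomistic distributions, which requires the user's own atomistic
  trajectories.
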