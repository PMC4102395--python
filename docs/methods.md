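# Methods

This note documents the models, conventions and numerical choices
behind `p450kit`, and what its synthetic-fixture tests do and do not
establish about real simulation data.

## Coordinate and unit conventions

All coordinates are in ångströms; energies in kcal/mol; times in
nanoseconds; temperatures in kelvin. Residue numbering is the author
(PDB) numbering and residue ranges are inclusive on both ends.
Trajectories default to a 0.02 ns frame spacing, the sampling interval
used for gating analyses. Two trajectory dialects are read and
written: multi-model PDB and multi-frame XYZ with a `t=<ns>` comment
tag. The PDB layer interprets only ATOM/HETATM/MODEL/ENDMDL records;
write∘read is the identity on those fields, with coordinates
quantised at the format's 10⁻³ Å precision. Atomic masses are IUPAC
2021 standard weights rounded to 4 significant figures; unknown
elements carry mass 0 and are only legal under unweighted centroids.

## Geometry primitives

Centres of mass default to unweighted heavy-atom centroids (the
mass-weighted variant is a flag) because coarse-grained and atomistic
structures differ in hydrogen content, and side-chain COM gating
distances must mean the same thing in both. Torsions follow the IUPAC
sign convention (clockwise positive looking down the central bond),
computed with the atan2 form and returned in (−180°, 180°]. Note the
torsion is *symmetric* under chain reversal and antisymmetric under
mirror reflection; the property tests assert exactly that.

RMSD and RMSF are computed after least-squares rigid-body superposition
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`) of each
frame onto the reference. For the "average" reference the fit is
two-pass: fit to frame 0, form the mean, refit to the mean — deviations
"from average positions" presume global motion has been removed. RMSD
is unweighted by default; whether published trajectory RMSDs are
mass-weighted is generally unstated, so the flag exists but stays off.

## Elastic networks

A bond joins every pair of backbone particles within the cutoff
(default 7 Å), with the equilibrium length frozen at the build-time
distance and a pass-through force constant — this module emits
topology, it never simulates, and no standard force constant exists to
bake in. Pairs within |Δres| ≤ 2 on the same chain are excluded: those
contacts belong to the bonded terms of a CG force field. The exclusion
window is configurable since conventions differ between CG models.
Cross-domain relaxation moves every bond with one endpoint in the
transmembrane range and the other in the globular range into a
`removed` set (conserving |bonds| + |removed|, idempotent). The TM
range is a required parameter with default 1–43 — immediately
preceding the membrane-anchoring segment at residues 44–47 — because
the modelled helix has no canonical printed bounds.

## Membrane geometry

Deformation surfaces bin phosphate positions on a 2 Å grid (default)
in a protein-fixed frame: each frame is superposed onto frame 0 via the
protein Cα set before binning, which makes the surface invariant under
rigid motion of the whole system. Leaflets split at the per-frame
phosphate midplane; `split_leaflets=False` supports single-sheet
fixtures. Empty cells are reported as missing (NaN, count 0), never
interpolated. The flat-plane report quantifies departure from the
planar-slab picture used by orientation databases: mean |deviation|,
maximum thickening and thinning.

The membrane normal defaults to the laboratory z axis (the usual setup
convention); `fit_membrane_normal` offers the smallest principal axis
of the phosphate covariance for tilted boxes.

Orientation vectors: v_c joins the Cα midpoints of residues 137–141
(helix C) and 207–211 (helix F); v_i joins the Cα midpoints of
292–296 and 321–325 (first and last turns of helix I). α and β are
the angles of v_c and v_i to the normal via arccos of normalised dot
products, so α(v) + α(−v) = 180° holds identically.

Heme tilt is the angle between the least-squares porphyrin plane
(SVD of the centred 24 ring-atom coordinates; the atom set is
configurable since published definitions rarely state whether Fe is
included) and the membrane plane: 0° when parallel, 90° when the heme
contains the normal, i.e. arccos|n̂·n̂_plane|. This plane–plane
convention matches the scale of reported experimental and simulated
tilts (tens of degrees); the complementary plane-vs-normal convention
is exposed as a flag.

Insertion depth is the signed distance of a selection's COM below the
mean phosphate z of the chosen leaflet (positive = buried), with an
`"all"` leaflet mode for single-sheet fixtures.

## Gating and active site

A gate is open in a frame when the unweighted COM separation of the
two gating side chains (heavy atoms Cβ onward; glycine is rejected) is
below the threshold, 7 Å by default. Percent-open reports pool
replicas by concatenating frames, and analyses conventionally use the
trailing 20 ns window of each run (`Trajectory.slice_time`), since
early frames carry the initial relaxation.

Propionate conformation is classified by the C3A-C2A-CAA-CBA torsion:
around +100° the chain sits on the distal ("up") face, around −100° on
the proximal ("down") face. Only those anchors are established, so the
natural separator is the sign, with the boundary assigned by
`≥ 0 → distal`. Salt bridges are minimum distances between the
propionate carboxylate oxygens and partner side-chain nitrogens
(arginine NE/NH1/NH2, tryptophan ring NE1); missing partners are
omitted with a warning rather than an error so partial models still
report. The Arg212 in/out label is a geometric proxy of this package's
own: "in" iff CZ is closer to the active-site centre (heme Fe by
default) than that residue's own Cα — the published descriptions of
the two conformers are qualitative only.

Substrate mobility vs gate opening: non-overlapping windows (≥ 10
frames) of the ferryl-O-to-substrate-COM distance yield per-window
variances, paired with per-window gate occupancy and summarised by a
Spearman rank correlation — rank-based because no distributional form
is claimed for the relation, which has only been shown graphically.
Degenerate cases (constant series, a single window) report the
correlation as undefined (None) instead of a number.

## QM/MM preparation

Truncation keeps a water or ion residue iff any of its atoms lies
within 5 Å (default) of any core atom, where "core" is anything not on
the water/ion/lipid residue-name lists (HOH/TIP3/SOL/WAT,
NA/CL/SOD/CLA/…, POPC/POPE; all overridable). Lipids are dropped
wholesale when the membrane flag is set — the heme is far from the
bilayer, so the membrane's direct electrostatic effect on the QM
region is negligible and excluding it cuts cost. The operation is
idempotent and never touches core atoms.

The QM region for Compound I keeps Fe, the ferryl oxygen, the 24-atom
porphine core, the proximal cysteine as SCH2 (Sγ, Cβ, Cβ hydrogens)
and optionally the substrate. "Without heme substituents" is realised
by severing the 8 ring–substituent bonds (two propionates, two vinyls,
four methyls) plus the cysteine Cβ–Cα bond, capping each with a
hydrogen link atom placed 1.09 Å (a standard C–H length; the link-atom
literature rarely prints a distance) along the severed bond vector.
QM charge and spin multiplicity are metadata (quartet = 4 by default;
only the quartet state is bookkept since doublet and quartet barriers
are effectively equal for hydrogen abstraction). The charge
bookkeeping for the severed (MM-charged) propionates is left to the
caller as configuration.

The mobility mask is residue-granular: a residue is mobile iff any of
its atoms is within the cutoff (5 Å default) of any QM atom; waters
count as single residues; everything else is fixed. The mask is
monotone in the cutoff.

Scan restraints enumerate the reaction-coordinate grid: start 1.8 Å,
ascending to 3.1 Å and descending to 0.9 Å in 0.1 Å steps (14- and
10-point legs sharing the start; 23 distinct targets), force constant
1000 kcal·mol⁻¹·Å⁻². Bounds that are not whole multiples of the step
from the start raise an error — no silent rounding. A separate
md-preparation restraint (target 1.2 Å, k = 100) is emitted as a
machine-readable spec, not engine input.

## Reaction energetics

`run_scan` performs adiabatic mapping over any deterministic energy
backend (position vector → energy, gradient). Each leg seeds every
restrained minimisation from the previous converged geometry;
minimisation is L-BFGS-B on E + k(r − r₀)², converged at max gradient
component ≤ 10⁻³ kcal·mol⁻¹·Å⁻¹ (configurable). The profile stores the
*physical* backend energy at each converged geometry — the restraint
term is excluded, because the barrier is defined on the potential
energy surface: barrier = max(E) − min(E), the transition state minus
the reactant complex. Backends here are analytic 1-D surfaces (the
bundled harmonic and double-well classes) or any user object honouring
the contract; the many-atom minimisation of a real QM/MM engine is out
of scope by design.

Barrier ensembles: mean is arithmetic; the standard deviation uses the
sample (n−1) denominator — the population form is inconsistent with
the reference aggregates the tests pin (it gives 3.1/2.3 where 3.4/2.6
is required). The Boltzmann-weighted average uses
kT = 0.0019872·T kcal/mol at a default T = 300 K with the log-sum-exp
form; direct computation confirms this reproduces all four reference
aggregates at printed precision, which fixes the operational
definition. The weighted average is bounded below by min(barriers) and
above by both the mean and min + kT·ln N, approaching min as T → 0 and
the mean as T → ∞ (tested numerically at 1 K and high T with the
second-order var/2kT correction as the tolerance).

Mulliken aggregation sums per-atom spin densities and charges into
fragments ({Fe, ferryl O, porphyrin, S/SCH2, substrate} typically);
every atom must be assigned to exactly one fragment and totals are
conserved exactly. Ensemble means and sample SDs are reported across
snapshot tables. Fe–S distance reports give mean and sample SD across
optimised structures, with SD undefined (None) for a single structure.

## Synthetic fixtures and what the tests show

Every generator is a pure function of (parameters, seed) and returns
metadata sufficient to predict each analysis's output without reading
coordinates back (ground-truth closure):

- **Helix**: ideal α-helix Cα trace (rise 1.5 Å, twist 100°/residue;
  radius chosen so Cα spacing is ≈ 3.8 Å) with dummy backbone atoms.
- **Lipid sheet**: phosphate pseudo-atoms on a grid at z₀ (default
  20 Å, a typical phosphate-plane height) minus an optional Gaussian
  dimple; mirrored leaflets on request.
- **Gate trajectory**: two phenylalanines whose side-chain COM
  separation switches between 5 Å (open) and 9 Å (closed) — straddling
  the 7 Å threshold — under a two-state Markov chain parameterised by
  stationary open probability and switching rate (a = rate·p,
  b = rate·(1−p)), seeded from the stationary law. Statistical
  recovery tests use a 3-standard-error band on the
  autocorrelation-corrected effective sample size n·rate/(2 − rate),
  not the naive binomial SE.
- **Toy Compound-I site**: planar porphine with PDB heme atom names,
  Fe, ferryl O, all eight substituent stubs, a cysteine fragment and a
  5-atom substrate carrying C10/H5. The propionate-A torsion is
  constructed at any requested angle by natural-extension (NeRF)
  placement, exact to < 10⁻⁶ °. The inventory metadata (35 QM atoms
  with substrate, 9 link bonds) is what the QM-region selector must
  reproduce.

These fixtures establish that the machinery is correct — brute-force
equivalences, parameter recovery, conservation laws, analytic limits —
at sizes of tens to a few hundred atoms and 10²–10⁴ frames. They do
not emulate force-field physics, lipid chemistry, conformational
heterogeneity or electronic structure, so passing tests say nothing
about ensemble observables that require engine trajectories and DFT:
measured heme tilts near 60–72°, Fe–S means of 2.6–2.7 Å, per-model
gate-open percentages of roughly 30–60%, or a transition state near an
O–H distance of 1.25 Å. For those, the package verifies the measuring
instruments on constructed inputs with known answers (e.g. a profile
built with its maximum at 1.25 Å is found there; a constructed 72°
tilt is recovered exactly).

Problem sizes in the shipped tests and the acceptance script —
200-particle clouds for the elastic brute force, 25×25 phosphate
sheets, 10⁴-frame Markov chains, 23-point scans over analytic
backends — were chosen as the smallest sizes at which the statistical
bands above are meaningful.

## Known limitations

- No binary trajectory formats (GRO/XTC/DCD); the Trajectory contract
  is the extension point.
- No bond perception: backbone flags and the heme substituent table are
  name-based conventions.
- The elastic-network force constant, QM charge and the treatment of
  active-site crystallographic waters during truncation are deliberate
  configuration points, not defaults — the conventions vary between
  studies and engines.
- The pipeline's `all` command runs on fixture systems; real studies
  drive the library functions on their own trajectories.
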