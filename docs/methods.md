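# Methods

## Scope and model overview

The package quantifies the dual-binding behaviour of a two-chain protein
complex (the motivating system is a cohesin–dockerin pair) at two levels:

1. a **rigid-body statistical analysis** of per-pose free energies
   ΔG(Z, φ) over a translation–rotation grid, aggregated into per-mode
   binding free energies and mode probabilities;
2. a **structure-based Cα coarse-grained model** with Langevin dynamics for
   thermal stability and single-molecule-style stretching.

The per-pose free energies themselves are produced by an external
side-chain-repacking energy backend and enter through a tabular interface
(TSV columns `k, z, phi, dG`); the package deliberately does not implement
an energy function of that kind.

## Symmetry axis and rigid poses

Two crystal forms of the same complex exemplify the two binding modes.
After superposing the first chains (the cohesins), each shared dockerin
helix residue contributes a vector from its mode-I to its mode-II Cα
position.  If the two modes are exactly related by a rotation about an axis,
all these vectors are perpendicular to it.  `find_symmetry_axis` therefore
minimises the summed squared axial components of the vectors over rotations
of the coordinate frame: each iteration solves the linearised least-squares
problem for the infinitesimal rotation (ω_x, ω_y) of the current frame,
applies it exactly, and stops when the residual improves by less than
1e-9 Å² (or errors out after 500 iterations, carrying the residual).  The
fixed point satisfies the eigenvector condition of Σ v vᵀ, and the test
suite cross-checks the result against that analytic solution.

Design choices the procedure leaves open, resolved as follows:

* **Helices used**: the first and third dockerin helices (residues 11–23 and
  45–56), the two that couple to the cohesin in both modes.
* **Frame origin**: the centroid of the paired helix Cα atoms (midpoint of
  the two modes).  Only the axis direction matters for the angle; the origin
  fixes where the axis passes.
* **Pose composition order**: a pose (Z, φ) rotates the dockerin by φ about
  the axis through the origin, then translates by Z along the axis.  The
  axis is oriented so positive Z moves the dockerin toward the cohesin.
* **Steric masking**: a pose is forbidden when any inter-chain heavy-atom
  pair comes closer than 2.0 Å — safely below any bonded or non-bonded
  contact distance.  Along a pure approach the mask is monotone (tested on
  convex toy bodies).
* **Grid defaults**: Z ∈ [−10, +4] Å step 0.5 Å, φ ∈ [−180°, 180°) step 2°;
  the reported minima (φ = 3°, 172–173°) imply an angular resolution of 3°
  or finer.

`mode_rotation_angle` reports the least-squares in-plane rotation of the
helix Cα sets about the axis, in [0°, 360°); forward and reverse angles sum
to 360°.

## Mode free energies and probabilities

With β = 1/(k_B T), k_B = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T in kelvin
(298 K and 308 K are the temperatures of interest),

F_mode = −k_B T log Σ exp(−β ΔG_k(Z, φ)) over all replicas k, all Z, and all
φ strictly inside the mode's angular interval (mode I: |φ| < 90°; mode II:
the complementary arc; the boundaries ±90° belong to neither mode), with
states above the cutoff E_c excluded.  Numerical contract: the sum is
evaluated by log-sum-exp and is exact to 1e-9 relative even at
βΔG ≈ −110, where naive exponentials overflow.  Sums are unweighted grid
sums, matching the discrete definition; no cell-area weighting is applied
(the supplied grids are uniform).

F is non-increasing in E_c and bounded between ΔG_min and
ΔG_min − k_B T ln N.  The **saturation value** is F at the largest scanned
E_c; the **plateau onset** is the smallest scanned cutoff from which F stays
within 0.05 kcal/mol of the saturation value for the rest of the scan.  Note
that a state far above the minimum (say 14 kcal/mol at room temperature)
carries a Boltzmann weight of ~1e-11 and cannot move F detectably; plateaus
therefore begin as soon as the thermally relevant states have entered, not
when the last state enters.

Mode probabilities: p_I/p_II = exp[−(F_I − F_II)/k_B T] with p_I + p_II = 1,
computed on the log scale so extreme ratios neither overflow nor lose
precision.  Ratios of this kind are conventionally quoted to one significant
figure; `round_to_one_significant_figure` implements that convention.

## Native contacts by the overlap criterion

Residues i and j are in native contact when any of their heavy-atom pairs
satisfies d(a, b) ≤ 1.24 × (r_vdw(a) + r_vdw(b)); the 1.24 factor
corresponds to the inflection point of the 12-6 Lennard-Jones potential and
is exposed as a parameter.  Sequence neighbours (i, i±1) and (i, i±2) are
excluded within a chain; inter-chain pairs never are.  Contacts are counted
at residue level (one contact per residue pair regardless of how many atom
pairs overlap), matching the one-bead-per-residue model.

The van der Waals radii are an atom-class table in the
Tsai–Taylor–Chothia tradition: sp³ carbon 1.88 Å, sp²/aromatic carbon
1.76 Å, nitrogen 1.64 Å, carbonyl-type oxygen 1.42 Å, hydroxyl oxygen
1.46 Å, sulfur 1.77 Å.  The exact class granularity used in published
counts is not always recoverable, and counts can shift by a few contacts
under defensible re-assignments (e.g. carboxylate vs hydroxyl oxygen); the
table is therefore overridable via a two-column text file and the class
assignment is unit-tested.  Bound Ca²⁺ ions are single spheres of radius
1.53 Å and contact dockerin residues by the same rule; an ion's contacts are
never sequence-excluded.

The production implementation uses a KD-tree pre-filter with an exact
per-pair radius test and is required (by test) to agree exactly with a
brute-force all-pairs scan on every fixture.

## The coarse-grained Hamiltonian

One bead per residue at the Cα position; each bound ion is an extra bead
tethered only through its native contacts (no bonds, no chirality), with the
same mass as residue beads.  Internal units: energy ε (≈110 pN·Å
≈ 1.58 kcal/mol), length Å, time τ (~1 ns), uniform mass m.

* **Bonds**: V = (k_bond/2)(r − r_nat)², k_bond = 100 ε/Å², between sequence
  neighbours.  The literature convention for the 1/2 factor varies; the
  spring constant here multiplies the half-squared displacement.
* **Native contacts**: V = 4ε[(σ_ij/r)¹² − (σ_ij/r)⁶] with
  σ_ij = r_nat/2^(1/6), so each contact is minimised (depth −ε) exactly at
  its native distance.
* **Non-native pairs** (everything not bonded and not native, including
  inter-chain): the truncated-and-shifted repulsive Lennard-Jones with
  σ = r₀/2^(1/6), r₀ = 4 Å — positive inside r₀, identically zero beyond,
  continuous at r₀.
* **Chirality**: per quadruplet of consecutive beads,
  V = (κ/2)(C − C_nat)² with C = [(v₁×v₂)·v₃]/d₀³, v the successive bond
  vectors and d₀ = 3.8 Å the canonical Cα–Cα distance.  κ = 1 ε by default.
  The exact historical form of this term is not fixed by the available
  description; the scalar-triple-product harmonic used here favours the
  native local handedness, vanishes at the native structure, and penalises
  the mirror image by 2κΣC_nat² — it is flagged as a modelling choice and
  κ is configurable.

Forces are fully analytic (including the chirality gradient) and are tested
against central finite differences to 1e-4 ε/Å; internal forces sum to zero
force and zero torque.

## Langevin dynamics

m r̈ = F − γ ṙ + Γ with γ = 2 m/τ (effectively overdamped) and Γ Gaussian
with per-component standard deviation √(2γk_BT/dt) when applied as a force
held over one step — the standard discretisation of noise with continuum
dispersion √(2γk_BT).  The default integrator is the fifth-order Gear
predictor–corrector (corrector coefficient α₀ = 3/16, appropriate for
velocity-dependent forces) at dt = 0.005 τ; a Langevin velocity-Verlet
(BAOAB) integrator is available behind `integrator="verlet"` and both pass
the conservation and equipartition suites.  With the thermostat off
(γ = 0, T = 0) energy drifts by less than 1e-4 ε over 10⁴ steps on a
10-bead helix.  Trajectories are bit-reproducible given the seed.

**Thermal stability.** P0 is the fraction of sampled frames (pooled over
time and trajectories) in which *every* native contact is present; Q is the
mean fraction of present contacts, so P0 ≤ Q always.  A contact counts as
present when r_ij < 1.5 σ_ij — the same cutoff the pulling protocol uses for
breaking, chosen so that "present" and "broken" are complementary across
protocols.  The sampling stride is configurable (default every 100 steps).
T0 is the P0 = 1/2 crossing by linear interpolation.

**Thermal unfolding.** A trajectory unfolds when all nonlocal contacts
(|i − j| > 4 in sequence; cross-chain and ion contacts always count as
nonlocal) are simultaneously broken; t_u is the median over trajectories.
Censored trajectories (no unfolding within the step budget) contribute +∞,
so the median is well-defined whenever more than half unfold, and the
unfolded fraction is reported alongside.

**Pulling.** Harmonic springs (K = 0.12 ε/Å² by default, ~1 pN/nm for a
typical AFM cantilever when K is read in ε-units — note that converting
0.12 ε/Å² with ε = 110 pN·Å literally gives ≈13 pN/Å, an inconsistency in
the source conventions; the ε-unit value is authoritative here) attach to
the N-terminal beads of the two chains; one anchor is fixed, the other moves
at v_p (5×10⁻⁵ Å/τ by default) along the initial inter-anchor direction.
The spring tension is averaged per 0.5 Å of anchor travel.  Contacts break
at r > 1.5 σ_ij, may re-form, and the displacement of the **last** break is
logged per contact.  Dissociation is declared when every interface contact
stays broken over a sustained 1 Å of further displacement.  Pulling runs at
T = 0.3 ε/k_B.

**Long/short classification.** Dissociation displacements of an ensemble
are split by an exact 1-D two-cluster (2-means) partition; the default
threshold is the midpoint between the two cluster means and is
user-overridable.  The report carries the long fraction with a binomial
(Clopper–Pearson) confidence interval and per-contact-class medians of the
last-break displacements.

## Synthetic data

The generators provide every input class with known ground truth:

* **Landscapes**: sums of Gaussian basins in (Z, φ) (circular in φ) on a
  baseline, with per-replica additive Gaussian jitter (default 1 kcal/mol,
  the scale of the scatter of basin depths across input-structure replicas
  seen in practice).  The default two-basin shape places a −38.2 kcal/mol
  basin at φ = 3° and a −28.7 kcal/mol basin at φ = 173° — the deepest
  replica values of the wild-type tail-truncated system.  The manifest
  stores the analytic minima and the mode-probability ratio by dense
  quadrature, which the grid aggregation must reproduce to ~1–2 % on a dense
  grid.
* **Toy structures**: ideal α-helices (rise 1.5 Å, twist 100°, radius
  2.3 Å → Cα–Cα ≈ 3.8 Å) decorated with a fixed alanine-like heavy-atom
  template (N, Cα, C, O, Cβ) — enough chemistry for the overlap criterion
  without side-chain modelling; hairpins (two strands and a turn) carrying
  nonlocal contacts for unfolding runs; and two-helix "complexes" with an
  interface for pose scans and pulling.
* **Rotated pairs**: a structure and its copy rotated by a known angle about
  a known axis (optionally with coordinate noise), for the axis/angle
  recovery tests.

What the generators do **not** emulate: real side-chain packing, sequence
heterogeneity, solvent effects, the ruggedness of real energy landscapes,
and crystallographic artefacts.  Passing tests therefore demonstrate the
correctness of the algorithms and statistics, not the biophysical accuracy
of any particular prediction on real structures.

## Problem sizes and numerical choices

The test and demonstration runs use deliberately small systems (6–56
residues, 2–9 trajectories, 10³–10⁵ steps) so the whole suite completes on a
single CPU in minutes; production-scale studies (hundreds of trajectories,
10⁵ τ each) are reachable through the same settings objects.  Statistical
assertions use ~3-standard-error windows at the sampled sizes.  Tie-breaks:
the minimum report returns the first grid cell in scan order among exact
ties; degenerate inputs (collinear point sets, empty selections, empty mode
regions, chain breaks > 4.5 Å) raise explicit errors rather than returning
silent defaults.

## Known limitations

* The rigid-body analysis inherits whatever biases the external energy
  backend has; backbone flexibility is outside its scope by construction.
* The chirality term's strength is a convention (1 ε), not a fitted value.
* The Gear integrator's kinetic temperature carries an O(γ dt) bias of
  order 1–2 % at the default settings; configurational averages agree with
  an independent BAOAB implementation to statistical precision.
* Contact counts on real structures are sensitive at the ±few-contact level
  to the oxygen/carbon class assignment of the radii table (see above).
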