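# Methods

## Model

A collagen gel is represented as an off-lattice, three-dimensional
bead-and-spring network. Each fiber is a straight chain of `n_b = 5`
beads joined by `n_b − 1 = 4` Hookean springs; inter-fiber crosslinkers
are additional Hookean springs between beads on different fibers. The
total elastic potential energy is

    U = Σ_springs ½ k (ΔL)²,   ΔL = |r_j − r_i| − L₀,

where the sum runs over fiber segments and crosslinks alike. Spring
constants follow the slender-rod law `k = E·A/L₀` with `E` the Young's
modulus, `A = π d²/4` the cross-section, and `L₀` the rest length.
Fiber segments use the fiber modulus (32 MPa) and the segment rest
length (25 µm for a 100 µm fiber); crosslinks use the crosslinker
modulus (the "strength" parameter) with the fiber's cross-section and
their own rest length. There is no bending or torsional stiffness, no
excluded volume, and no fiber–wall interaction: the energy is purely
Hookean stretch. Consequently a straight, tension-free fiber has zero
transverse stiffness, which shapes both the mechanics (long toe
regions, non-affine rearrangement) and the numerics (see below).

Assumptions inherited with the model: quasi-static (zero strain rate)
loading, so viscous effects are ignored — appropriate for strain rates
of migrating cells, orders of magnitude below rheometer rates; no
breakage, so results are meaningful up to the plastic regime only;
homogeneous fiber length and width.

## Network construction

The fiber count at a bulk collagen concentration ρ (mg/ml) follows
from the fibril molecular weight (8.05×10⁵ g/mol) and the cylinder
volumes of fibril (300 nm × 1.5 nm) and fiber (100 µm × 0.3 µm):
`N = round(ρ·V_box / m_fiber)`; the default 200×200×300 µm box holds
673 fibers per mg/ml. Fiber centers are uniform in the box and
orientations uniform on the sphere (random geometry) or fixed along +z
(prealigned). Beads may protrude through the walls; rejecting
protruding fibers would bias orientations near the boundary.

Crosslinkers are placed by rejection sampling of bead pairs: a pair is
accepted if the beads sit on different fibers, their distance lies in
the binding window (0.45–50 µm), neither bead already carries 10
crosslinks, and the pair is not already linked. The crosslinker count
is `round(density · N)` where the density parameter is expressed in
multiples of the fiber count (the `×N` unit). A crosslink's rest
length is its length at creation, so a freshly built network is an
exact energy minimum — no initial relaxation step is needed and the
initial stress is identically zero.

Two modelling choices here were genuinely open:

* **Crosslink stiffness length.** `k = E_xl·A/L₀` uses the actual
  crosslink rest length, so short crosslinks are stiffer. The
  alternative (a fixed reference length for all crosslinks) raises all
  moduli by roughly 1.4× at the calibrated parameters but does not
  change any qualitative behavior; the per-length convention is the
  physically standard one for an elastic rod and is used throughout.
* **Zero insertion prestress.** Nothing in the model fixes the initial
  crosslink tension; zero prestress is the unique choice for which the
  generated state is an equilibrium.

## Relaxation and the quasi-equilibrium criterion

After each imposed boundary displacement the free beads are relaxed
until the maximum per-bead force drops below 10⁻⁵ of its value in the
strained state (the configuration immediately after the displacement),
with an absolute floor of 10⁻⁹ nN guarding near-zero baselines. Only
free beads move; anchored beads translate rigidly with their grip and
report reaction forces.

The default engine is a limited-memory BFGS (memory 10) compiled with
numba, taking the unit quasi-Newton step with Armijo backtracking. A
preconditioned Polak–Ribière+ conjugate-gradient engine with a secant
line search is provided as `minimize(..., method="cg")`; both stop at
the same force criterion and are cross-validated against each other
and against a fine-step gradient-descent oracle in the test suite.
L-BFGS is the default because it reaches the criterion in roughly half
the gradient evaluations on typical strained networks (≈4.7k vs ≈7.9k
per 0.01 strain step at 1 mg/ml) and the compiled driver removes the
remaining interpreter overhead, about a 3× wall-clock advantage.

Because tension-free straight fibers have zero transverse stiffness,
the energy landscape has broad, nearly flat valleys. Two consequences
are documented rather than hidden:

* Different descent paths stopped at the *relative* force criterion can
  retain slightly different residual energies (≈0.2% on well-connected
  networks, more on sparse ones). Macroscopic observables (stress,
  moduli, Poisson's ratio) agree between engines to well within
  replicate spread.
* Equality checks between engines and the gradient-descent oracle are
  therefore performed at a deep *absolute* force floor (10⁻⁵ nN),
  where all three agree to better than 10⁻⁴ relative energy.

The relaxation starts from an affine displacement guess for the free
beads (linear interpolation of the boundary motion). This only
accelerates convergence; the converged state is defined by the energy
and the criterion, not by the guess.

## Loading protocols

Strain is defined relative to the free height between the grips
(200 µm by default), so one 0.01 strain step moves the top grip by
exactly 2 µm. Shear translates the top grip along +y with the bottom
fixed; tension moves top and bottom apart symmetrically along z, half
a step each. Anchor membership is decided once, on the initial
configuration, by bead height (bottom/top 50 µm slabs; 50 µm is half a
fiber length, the saturation depth — deeper grips do not change the
measured moduli, shallower ones anchor too few fibers and read low).
The local-deformation (poke) test anchors a 20 µm cube of beads at the
center of a 300³ µm box and every bead within 50 µm of any wall, then
drags the cube upward 60 µm in 2 µm steps.

## Observables

**Stress** is the spring-force flux through the horizontal mid-plane:
each spring whose endpoints straddle z = H/2 contributes the component
of its tension along the loading axis (oriented lower→upper), and the
sum is divided by the full box cross-section (Pa). At equilibrium this
equals the grip reaction force over the same area; the test suite
asserts the identity at every converged step, within the residual-force
budget allowed by the convergence criterion.

**Moduli** are ordinary least-squares slopes of stress vs strain over
the 0.01–0.10 window (10 steps of 0.01).

**Poisson's ratio** is measured from a rectangular lateral box fitted
at nine heights (50, 75, …, 250 µm): at each plane, within a ±12.5 µm
slab, the 2.5%-of-fiber-count outermost beads per side define the box
edge as the mean of their coordinates. The boundary beads are selected
once on the zero-strain reference state and *tracked* through the
deformation. Re-selecting extremes on the deformed state is biased:
axial stretch dilutes the beads per fixed slab, which shrinks the
mean-of-extremes width estimate and inflates the apparent contraction
(a synthetic affine test with ν = 0.30 reads 0.44 with re-selection
and exactly 0.30 with tracking). The tracked estimator is exact under
affine deformations and is used everywhere.

**Force statistics** report the mean force magnitude and histogram per
bead group (poke cube, anchored layer, interior).

## Calibration

Simulated shear moduli over a grid of crosslinker strength (50–800 kPa,
step 50) and density (2–16N, step 2), at the four experimental collagen
concentrations, are compared with bulk rheology moduli (3.03, 44.50,
97.38, 123.5 Pa at 1–4 mg/ml; shipped as a packaged CSV) through the
sum of squared residuals. The SSR surface is refined by iterated
bicubic spline interpolation on grids of halved spacing (7 iterations
by default), local minima are collected (grid points not exceeded by
any neighbor, boundary minima flagged), and candidate minima are
re-simulated to pick the best fit. The calibrated values used as
package defaults are 634.38 kPa and 11.18N. Replicate aggregation uses
the mean (5 replicates by default). The full 16×8×4-density sweep is a
long-running job exposed through the CLI; the test suite exercises the
pipeline on a reduced 3×3 grid in a 120×120×220 µm box and asserts the
strength–density trade-off (negative rank correlation along the valley
floor) rather than the exact optimum, which is ensemble-dependent.

## Problem sizes used in the shipped tests and acceptance script

Full-scale geometry (200×200×300 µm, five beads per 100 µm fiber) is
used for every headline quantity: Poisson's ratios (3 seeds per case;
0.01 strain and 50-step runs to 0.5 strain), the rigidity-transition
sweep (8 densities × 2 seeds), the calibrated moduli (5 seeds at 2 and
3 mg/ml), and the poke test (300³ µm box, full 60 µm displacement,
2 seeds). Reduced scales appear only where the quantity is a
qualitative property: the anchor-depth saturation check uses a 150×150
µm cross-section (the effect lives in the z direction), and the SSR
valley check uses the reduced sweep above. The deep minimizer
cross-check runs on a 50-fiber network in a 60×60×90 µm box.

## Known limitations

* The calibrated model reproduces the experimental 2 mg/ml shear
  modulus to ≈10% but falls ≈35% short at 3 mg/ml: with a
  density-independent crosslink-length distribution (a property of
  Poisson-distributed straight fibers), the modulus grows close to
  linearly with collagen density, weaker than the experimental
  2→3 mg/ml ratio of ≈2.2. Matching that ratio would require a
  connectivity mechanism that depletes load paths at low density
  beyond what this construction produces.
* The Poisson's ratio of the prealigned network at 0.5 strain measures
  ≈0.19 with the tracked estimator (vs ≈0.25–0.28 with re-selection);
  the estimator was fixed once, on the affine-exactness argument, not
  per observable.
* Mean forces on the poke cube involve only ~7 beads at 2 mg/ml and
  scatter by ±20% across seeds.
* No viscoelasticity, breakage, bending stiffness, or heterogeneous
  fiber geometry; periodic boundaries are not supported.
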