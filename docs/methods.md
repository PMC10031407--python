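# Methods

This note records the models behind `wingsense`, the choices made where the
design was genuinely open, and what the package's synthetic data can and
cannot say about real wings.

## Structural model

The wing is a linear Kirchhoff–Love plate — transverse deflection only —
clamped along its base edge and free elsewhere, discretised with
Bogner–Fox–Schmit (BFS) rectangles: C¹-conforming Hermite-bicubic elements
with four degrees of freedom per node (w, w_x, w_y, w_xy).  On the uniform
1 mm mesh every element shares one reference stiffness block scaled by the
element's bending rigidity D = E h³ / 12(1−ν²), with E taken as the mean of
the four corner-node moduli of the stiffness field.  The consistent mass
matrix is used throughout.  BFS elements converge very fast here: refining
from 25 × 50 to 50 × 100 elements moves the first eigenfrequency and the
peak flapping tip displacement by ~10⁻³ % (the package's mesh-convergence
check).

**Stiffness field.**  E(x, y) = E_c · 10^(−m_x x − m_y y) normalised by the
*discrete* grid mean, so the sampled moduli average to E_c exactly; the
log-range identity log₁₀(E_max/E_min) = m_x·span + m_y·chord holds to
floating-point accuracy.  With the default decline rates the modulus spans
two orders of magnitude from the leading-edge base corner to the
trailing-edge tip corner.  A consequence worth knowing: at matched mean
stiffness the gradient wing has a *higher* first eigenfrequency than the
uniform wing, because the gradient concentrates stiffness at the root where
mode-1 curvature is largest.

**Rigid-body forcing.**  The plate lives in the co-rotating wing frame.
All rotation axes — the flapping axis and the body roll/pitch/yaw axes —
pass through one point on the clamped edge at mid-chord (a centred gimbal
mount; the chordwise station is exposed as
`Kinematics.axis_chord_position`).  For a material point r = (x, y−y_c, 0)
the transverse inertial load is exactly

    a_z = ω̇_x (y−y_c) − ω̇_y x + ω_z (ω_x x + ω_y (y−y_c)),

with ω the total angular velocity (flapping plus ramped body rotation)
expressed in wing coordinates.  Flapping enters through −φ̈ x; a yaw
rotation Ω adds the Coriolis-type term 2Ωφ̇ cosφ·(y−y_c) — a chordwise-
antisymmetric (torsional) load, the classic mechanism by which body
rotations twist flapping wings — plus an O(Ω²) term; pitch swaps the phase
(2Ωφ̇ sinφ); roll is parallel to the flapping axis and adds nothing
transverse once its ramp ends.  Three consequences:

* the yaw strain perturbation is ~2.5 orders of magnitude below the
  flapping strain in this surrogate (the 3-D solid model it stands in for
  reports ~3; a thin plate twists more readily than a solid, so its
  torsional response is relatively larger);
* the roll condition is undetectable at steady state *by construction* in a
  transverse-only plate — detecting roll requires membrane (in-plane)
  strain pathways that a Kirchhoff model deliberately omits;
* the choice of axis station matters: an off-centre origin would add a
  spurious spatially-uniform load component to the yaw drive.

Coriolis coupling of the plate's own transverse velocity has no transverse
component and drops out of the linear model; spin softening and stress
stiffening are not modelled.

**Damping.**  Total coefficient c = 2ζmω_n, with ω_n the first structural
eigenfrequency recomputed for every stiffness configuration (deterministic
Lanczos start vector, so repeated runs are bit-identical).  c is
distributed as mass-proportional damping C = (c/m)·M, which reproduces the
total force contract exactly: the summed nodal damping force on any rigid
transverse velocity V is −cV.  Note that mass-proportional damping gives
mode-k damping ratios ζ_k = ζ·ω_n/ω_k, i.e. higher modes are relatively
less damped.

**Time integration.**  Backward Euler (BDF order 1) at Δt = 0.2 ms on the
first-order form; the iteration matrix M + ΔtC + Δt²K is factorised once
per condition.  Backward Euler is dissipative, so free-vibration energy is
non-increasing step to step (a property test).  Its numerical damping is
also the dominant discretisation error: halving Δt changes the steady
wingbeat strain by ~3%, and successive halvings shrink that change
linearly in Δt, the expected first-order signature.  The scheme and step
are kept as stated study conditions rather than "fixed", since every
condition shares the same bias.

**Transients and the analysis window.**  The wing starts at rest; any body
rotation ramps from 0 to its full rate over one wingbeat with a half-cosine
(C¹) ramp.  Simulation proceeds wingbeat by wingbeat until the strain of
the last two cycles agrees to 1% of the overall amplitude (typically 6
cycles at ζ = 2; capped at 10, with a recorded warning if the cap is hit),
and the final full wingbeat — a half-open [start, end) window — is
analysed.  When two motion conditions are compared, both are simulated for
the same number of cycles so residual transients are common mode and cancel
in the class difference.  Overdamped wings converge *slower* than one might
expect: the slow real pole of an overdamped mode decays at
ω_n(ζ−√(ζ²−1)), about 0.27 ω_n at ζ = 2.

**Strain output.**  Spanwise surface strain ε_xx = −(h/2)·∂²w/∂x² on the
top surface, evaluated per node from the Hermite end-curvature of the
spanwise intervals meeting there (averaged at interior nodes).  The sign
convention is fixed; classification is invariant to a global flip.

## Spiking encoder

Each node carries a linear–nonlinear–Bernoulli sensor.  The temporal
feature cos(2πω(s−τ))·exp(−(s−τ)²/δ²) is sampled as a causal kernel on the
lag grid [0, τ+4δ] (≈21 ms, 0.1 ms bins), peaking at lag τ = 5 ms; solver
strain is linearly resampled to the bin grid and convolved causally.  The
convolution is the plain discrete sample sum — no bin-width scaling — which
keeps the filtered strain on the scale the sigmoid constants α = 5·10⁵ and
β = 10⁻⁴ were calibrated against; with it, the encoder operates in the
regime the published constants imply (filtered strain peaks a small
multiple of β; near-threshold sensors show intermediate firing
probabilities over a few bins).

Spikes are drawn once per 0.1 ms bin (probability > uniform variate),
under a 15 ms absolute refractory period that carries across wingbeat
boundaries; generation starts one refractory period before the analysis
window so refractoriness is warm.  The first-spike latency is stamped with
the end time of its bin, so in-window latencies lie in (0, 40] ms and 0
unambiguously encodes "no spike".  All trials of a condition come from one
PCG64 stream in a fixed (trial, node, bin) draw order over the full grid,
so a node's spike train never depends on which other nodes are read out,
and a fixed seed reproduces spike data bit for bit.

With simulated strain and default parameters, ~97% of (trial, node) pairs
spike; strongly driven sensors fire deterministically at the refractory
limit while sensors whose filtered strain grazes β carry the stochastic
timing code — and those near-threshold sensors are where rotation
information concentrates, since a small strain offset shifts their firing
probability by an O(1) amount.

## Sensor placement and evaluation

The SSPOC stage standardises the pooled two-class training matrix per node
(nodes constant across trials — e.g. never-spiking sensors — map to zero
rather than being dropped, keeping indices stable), computes a pooled
3-component PCA basis Ψ (deterministic sign convention), an LDA direction
w in that subspace (within-class scatter with a 10⁻⁶ trace-scaled ridge;
unit norm; rotation class positive), and solves the elastic-net
constrained program

    min λ‖s‖₁ + (1−λ)‖s‖₂²  subject to  Ψᵀs = w.

The ‖·‖₂ term is implemented as the squared Euclidean norm (standard
elastic-net ridge).  The program is solved through its Lagrangian dual:
minimising over s for fixed multipliers ν separates per coordinate into a
soft-threshold map, leaving a smooth convex dual in only m = 3 variables,
minimised by semismooth Newton with a BFGS fallback; the feasibility
residual ‖Ψᵀs − w‖∞ of an accepted solution is below 10⁻⁶ (typically
10⁻¹⁰).  The λ = 1 boundary is a linear program (HiGHS).  The top-10
nodes by |s| (ties to the lower index) form the sensor set.

**Operating regime of standardised SSPOC.**  Standardisation maps every
node to unit total variance, so the pooled PCA can only see class structure
that is *correlated across nodes*: a lone informative node, however
separable, becomes the minimum-variance direction of the pooled data and is
systematically invisible to the basis.  The method works on wing strain
precisely because strain fields are spatially smooth — hundreds of nodes
shift their spike timing coherently, and that correlated component
dominates the leading principal components.  Tests of single-node
recoverability therefore use small grids (where a 3-dimensional basis still
overlaps the informative direction) or probe the elastic-net stage with a
basis containing it.

Evaluation re-fits a 1-D Fisher projection on the *non-standardised*
training latencies of the selected sensors, places the decision boundary at
the midpoint of the projected class centroids, and scores the held-out 10%
of trials.  Each of the 20 iterations redraws the 90/10 split *and* the
spike-generation streams; strain is deterministic and shared.  Placement
sensitivity divides optimised accuracy by the mean accuracy of 20 random
10-sensor draws (a count chosen to mirror the 20 optimisation iterations)
and subtracts one.

## Modal analysis

POD is the SVD of the (node × time) analysis-wingbeat matrix; eigenvalues
are squared singular values normalised to sum 1.  The per-node temporal
mean is retained by default (spiking depends on absolute strain), with
mean-removal available as a switch.  For accuracy-versus-modes curves the
spatial basis is computed from the flap-only condition and applied to both
conditions as a spatial projector U_k U_kᵀ on the whole strain record, so
the pre-window filtering history stays consistent with the truncation.  In
this surrogate the yaw signature is torsion-dominated and enters with the
first torsional strain mode (mode 4 of the gradient wing at 3 GPa —
accuracy jumps from ~0.55 at k ≤ 3 to ~0.94 at k = 4); the flapping strain
itself is ≥99.9% captured by two spanwise-bending modes.

## Synthetic data and what it shows

The wing model *is* the data generator: periodic flapping strain with a
rotation-induced perturbation orders of magnitude smaller, spatially
structured by the stiffness field, with all trial-to-trial variability
introduced by stochastic spike generation.  What it does not emulate:
aerodynamic loading and fluid–structure interaction, membrane strain (and
hence steady-state roll detectability), geometric nonlinearity, venation,
realistic planforms, and sensor biophysics beyond the LN-Bernoulli
abstraction.  Passing tests therefore demonstrate properties of this
model family — not of real wings, whose strain fields are richer; the
package's claims are about how stiffness gradients and damping shape
*detectability within the model*.

Problem sizes used by the test suite and the acceptance script: the full
26 × 51 grid with 100 trials per condition and 20 optimisation iterations
for the headline detection number; coarse 5 × 10-element plates and
Gaussian latency fixtures for module-level tests.

## Known limitations

* Backward Euler at 0.2 ms carries a few-percent amplitude bias at the
  flapping harmonics (shared by all conditions).
* Roll detection is structurally absent (transverse-only plate).
* The yaw strain-perturbation ratio is ~10^2.4, somewhat larger relative
  to flapping than a 3-D solid wing would give (thin plates twist more
  readily).
* The discrete convolution convention and the spike-time bin-stamp are
  fixed conventions of this implementation; absolute latencies shift by a
  bin under other reasonable conventions, class differences do not.
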