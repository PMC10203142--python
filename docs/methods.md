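# Methods

cardiokit implements, at desk scale, the numerical core of a coupled
fluid–structure–electrophysiology heart simulator together with the
cohort-sizing mathematics of in-silico clinical trials.  Everything runs
on synthetic geometry generated by the package itself; the point of the
desk scale is that every physical and numerical claim is testable in
seconds to minutes on one CPU.

## Electrophysiology

**Tissue model.** The transmembrane potential obeys the bidomain
equations

    chi (Cm dv/dt + I_ion(s) + I_s) = div(Mi grad v) + div(Mi grad ve)
    0 = div(Mi grad v) + div((Mi + Me) grad ve)

with orthotropic conductivity tensors M = m_par e e^T + m_sheet s s^T +
m_norm n n^T built from per-cell fiber triads.  When Me = lam Mi, the
system reduces to the monodomain equation with M = lam/(1+lam) Mi; the
fast conduction bundles and the Purkinje network are treated that way and
their registry rows carry the already-reduced conductivities.  The
built-in conductivity registry lists the ventricular and atrial
intra/extracellular triples (mS/mm), the Purkinje scalar 3.95 and the
internodal-bundle scalar 1.29, together with the conduction speeds those
rows were calibrated against (0.5, 4.0 and 1.54 m/s).  The atrial
intra/extracellular anisotropy ratios are not proportional (0.66/0.18 !=
0.25/0.02), so atrial tissue defaults to the full bidomain; 1D studies
may use the harmonic-mean monodomain equivalent m_i m_e/(m_i+m_e), which
the test suite verifies agrees with the 1D bidomain to < 1 % in
conduction velocity.

**Discretization.** A two-point-flux finite-volume scheme on a generic
cell/face mesh; 1D cables, 2D sheets, 3D voxel slabs and the 1D
conduction-network graph all share one assembly (2D sheets use square FV
cells).  Faces carry the harmonic mean of the two face-normal
conductivities, which makes the operator conservative by construction
(total charge drift < 1e-10 per run under zero-flux boundaries).  Time
uses Godunov splitting: a Rush–Larsen/forward-Euler reaction step per
cell, then a theta-implicit diffusion solve (Crank–Nicolson by default,
factorized once per dt).  Outer boundaries are homogeneous Neumann; the
bidomain elliptic solve pins one cell and restores a zero-mean gauge.

**Membrane models.** Four registered models: a minimal two-variable
polynomial model (dimensionless v in [0,1], one recovery variable,
defaults k=8, a=b=0.15, gamma=0.002, mu1=0.2, mu2=0.3, time scale
12.9 ms per unit; documented rescaling v_mV = 100 v − 85), and three
biophysical human models — ventricular (19 states), atrial (21 states)
and Purkinje (20 states, auto-rhythmic).  Registered rest states are
fixed points of each module's own right-hand side, obtained by relaxing
or Newton-polishing the published initial conditions (residual <
1e-7/ms); the Purkinje equilibrium is genuine but unstable, which is the
physiology of a pacemaking cell, and the published paced-diastole state
is kept alongside for beating simulations.  Activation is detected as
the upward crossing of −40 mV (biophysical models) or v = 0.5 (minimal),
linearly interpolated in time.  The −40 mV level was chosen because
under electrotonic load on a fine cable the atrial action-potential peak
sits near −8 mV, so a 0 mV detector misses healthy propagation.

**chi·Cm calibration.** The tables fix conductivities but not chi and Cm
individually, so the product chi·Cm is one calibration scalar per
tissue.  `calibrate_chi_cm` bisects it (geometrically, since CV ~
sqrt(m/chi·Cm)) until a 20 mm cable at 0.1 mm resolution conducts at a
stated speed.  The headline transfer check calibrates the atrial model
at 0.5 m/s on the harmonic-mean atrial conductivity and then re-runs the
identical cable at the bundle conductivity 1.29 mS/mm; the sqrt(m)
scaling predicts 1.51 m/s and the solver measures ≈1.55 m/s, both within
5 % of the tabulated 1.54 m/s.  The atrial model is used here because at
1.54 m/s the minimal model's slow upstroke would need so much
diffusivity that the stimulus transient contaminates a 20 mm cable.

**Conduction system.** Slender bundles are 1D segment chains joined at
named junctions and coupled to the myocardium only through small
"insertion" faces, distributed over the distal segment cells so a single
junction cell is not clamped by the cold myocardial load.  Named block
switches sever junction links (a left-bundle block is one switch).  The
AV-node transit delay is a configurable calibration target (default
100 ms) hit by bisection on the nodal conductivity of a slow segment
that uses the standard (slow-kinetics) minimal model.  In the `mini_heart`
fixture the network cells run the minimal model with a shortened time
scale (2 ms/unit): bundle cells have fast upstrokes, and at desk
resolution this is what keeps a 1.29 mS/mm bundle regenerative rather
than decremental.

## Passive and active mechanics

Elements (tetrahedra for walls, triangles with a thickness for
membranes, two-node bars for 1D benchmarks) store their rest metric and
a material fiber frame.  The Fung energy W = c/2 (exp(Q) − 1), Q =
a_par e_par^2 + a_sheet e_sheet^2 + a_norm e_norm^2 acts on Green-strain
components in that frame; the per-tissue constants (left/right
ventricle and atrium, vessels, the two valve groups) live in an
immutable registry.  Nodal forces are the exact analytic gradient of the
assembled energy (second Piola stress S = c e^Q sum_i a_i e_i d_i d_i^T,
first Piola P = F S, scattered through the linear shape functions), so
internal forces match a central-difference gradient to 1e-6 and conserve
linear momentum to round-off.  Q > 700 raises instead of overflowing.

Active contraction is the fiber-aligned first Piola stress P_act =
Ta (F e_par) ⊗ e_par — the gradient of the objective energy Ta·e_par per
unit rest volume — so each element's active force set has zero net force
and torque, and a free fiber-aligned bar shortens until
dW/de + Ta = 0.  Cross-section conventions use the rest configuration.
Active tension follows the two-level relaxation dTa/dt = eps(v)(k_Ta v −
Ta) on the normalized potential, with defaults k_Ta = 47.9 kPa, eps = 1
below v* = 0.05 and 0.1 above, on the minimal model's time scale.

Node dynamics m_n x'' = F_ext + F_int + F_act advance with the two-step
Adams–Bashforth rule applied to both velocity and position (the blended
"AB2 velocity + backward position" variant was measurably dissipative —
18 % energy loss over ten oscillator periods — while pure AB2 keeps the
drift under 1 %).  Optional linear velocity damping (default 0) is
available and every test that uses it states its value.  Tissue density
defaults to 1060 kg/m^3.

## Hemodynamics

Incompressible Navier–Stokes (rho = 1060 kg/m^3, mu = 3.5 mPa s
Newtonian; a Carreau–Yasuda law with standard blood constants is
available) on a 2D staggered MAC grid: AB2 convection, Crank–Nicolson
viscosity (sparse factorized Helmholtz solves), and a pressure-Poisson
projection via a pinned sparse LU with zero-mean gauge — the projection
residual is at direct-solver level, and the discrete divergence stays
below 1e-8 every step.  x is periodic; y may be periodic, free-slip or
no-slip.  The production-scale 3D grid is out of scope by design; the
2D solver reproduces Taylor–Green decay to 0.2 % at 64^2 and plane
Poiseuille to < 1 %.  (The Poisson contract is met with a direct sparse
factorization rather than trigonometric transforms: identical contract,
simpler code at <= 96^2.)

**Immersed boundary.** Linear-basis moving-least-squares transfer on a
3-wide node stencil with Gaussian weights: constants and linear fields
reproduce exactly, interpolation is O(h^2), and spreading uses the
transposed weights, making the pair an exact adjoint and conserving the
total transferred force.  Direct forcing (U_target − u)/dt is iterated
*around* the projection (default 6 passes): forcing alone leaves
interp(spread(du)) != du, and projecting alone re-opens through-flow, so
the two alternate; the residual slip of a stationary plate in a unit
stream is then < 5 % of the free stream at 64^2.

**Loads and outlets.** Hydrodynamic loads are evaluated at wet-surface
markers: two-sided for leaflets, F = [−(p+ − p−) n + (tau+ − tau−)·n] A
with probes offset 1.5 grid spacings along ±n, one-sided for closed
chamber walls; a hydrostatic field on a closed sphere reproduces the
divergence-theorem resultant to < 2 %.  Outlets carry the
three-element-Windkessel volume forcing −f_WK = alpha u + beta
int u dt + gamma n on cylindrical subdomains, with the per-outlet
constants (aorta, coronary, pulmonary veins/artery, venae cavae) in the
registry; the per-face history integral uses the trapezoidal rule and
resets per run.

## Coupling

Loose coupling solves fluid (with last-step interface kinematics) and
electrophysiology first, then advances the structure once — cheap but
stable only below a dt set by the structural eigenperiod and the
added-mass ratio, which is the scheme's documented trade-off.  Strong
coupling repeats the fluid-load/structure-advance pass from the same
initial state with Aitken-relaxed mid-step interface kinematics until
the maximum relative change of node positions *and* velocities (max
norm, epsilon 1e-12) falls below the tolerance (default 1e-4).  Plain
fixed-point diverges when the fluid added mass rivals the structural
inertia; the dynamic relaxation restores convergence.  On the
membrane-in-channel fixture the count — which includes the initial
predictor pass — is typically 4 (about 3 corrections) and never exceeds
6; the count is dt-independent because the contraction rate is set by
the mass ratio.  The corrector residual decreases strictly, and the two
schemes agree to O(dt).  EP substepping (an integer divisor of the
mechanics/fluid step) is supported by the driver configuration.

## Synthetic ECG

Surface potentials use the infinite-medium lead-field integral V_s =
−K ∫ grad v · grad(1/|x − x_s|) dx with one-point (cell centroid)
quadrature and weighted-least-squares per-cell gradients; K is not
observable at desk scale and defaults to 1 (arbitrary units — only
timings, ratios and symmetries are asserted).  Leads must clear the
mesh by 5 cell sizes.  The quadrature matches the analytic dipole
potential −K p·r_hat/r^2 to < 5 % beyond 10 cell sizes and decays as
1/r^2; note that this check feeds an explicitly constructed two-cell
gradient field, because the least-squares reconstruction of an isolated
interior dipole produces compensating gradients whose lead integral
cancels analytically (the physical signal comes from wavefronts, whose
depolarized region reaches the tissue boundary).  QRS-like durations are
measured either as the activation spread (last minus first activation)
or from the trace at 5 % (configurable) of the beat maximum.

## Trial statistics

The cohort-size calculators implement the printed error models exactly:
plain Monte Carlo N^-1/2 (400 patients for 5 %, 10000 for 1 %),
variance-reduced C N^-1/2 with C <= 1, quasi-random N^-alpha with alpha
in [1/2, 1], rare-event Monte Carlo (pN)^-1/2, and Subset Simulation
log10(1/p)/sqrt(N) — the base-10 logarithm is chosen because it
reproduces the 400-vs-10000 rare-event comparison at p = 1e-2 exactly.
The illustrative variance-reduced/quasi-random pairing (C = 0.08,
alpha = 0.7 giving N = 50/500) is not reproducible from those formulas
as printed, so it is implemented as stated and not asserted.  These are
error models, not samplers.

## Fixtures and what the desk scale does not show

All geometry is synthetic: cables, sheets (uniform fiber angle, the
atrial rule), slabs (fiber angle rotating linearly from +60° to −60°
across the wall, the ventricular rule), a truncated prolate-spheroid
ventricle shell with circumferential/transmural fiber rules, a
membrane-in-channel FSI toy (per-unit-depth 2D convention, 1 mm
thickness, clamped anchor), torso leads at a 35 mm heart-to-skin
clearance, and a `mini_heart` (ventricle shell + His/bundle-branch graph
+ two leads).  Generation is pure — identical spec and seed give
byte-identical output — and the seed lands in the run manifest.

Problem sizes are the package's own choices: 20 mm/0.1 mm cables, 64^2
fluid grids, a ~1500-cell ventricle shell at 1.5 mm voxels, ~500-step
FSI runs.  Passing tests therefore demonstrate the governing equations,
discretizations and couplings — conduction-velocity calibration
transfer, conservation laws, convergence orders, activation-order
phenomenology of bundle block and resynchronization pacing — not
clinical-grade organ outputs: ejection fractions, chamber pressures and
12-lead morphology require the full-resolution anatomical model and are
deliberately outside this package's claims.  Known limitations beyond
scale: the 2D fluid solver cannot capture 3D intraventricular flow;
membrane models are single-variant (no drug block or restitution
protocols); the isotropic-kernel ECG ignores torso heterogeneity; and
the spring-network mechanics, while energetically consistent with the
Fung law on linear elements, is not a finite-element continuum
discretization.
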