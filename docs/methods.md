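# Methods

## Model

The package simulates regulated intracellular transport in a planar tube
domain Ω (a neuron's axon/dendrite network).  Three species are tracked:
free particles `n0`, and anterograde/retrograde attached particles `n+`,
`n-` moving with velocities `v+`, `v-`.  Attachment (`k±`), detachment
(`k'±`) and diffusion (`D±`) couple the pools; the microtubule densities
`l±(x)` scale the attached populations (`w± = l± n±` is the advected
quantity).  The momentum-like balance for the transport velocities
carries a concentration-gradient forcing `−∇n±` (motors slow down in
crowded regions), a traffic viscosity `μ`, and the control force `f±`.

Transport regulation is modeled as optimal control: minimize

    J = 1/2 ∫ (v± − V±)²  +  α/2 ∫ ‖∇n±‖²  +  β/2 ∫ f±²

subject to the transport system, with inlet loading `n0 = n_i`,
`n+ = λ_i n_i`, outlet data `n0 = n_o`, `n- = λ_o n_o`, transport
velocities pinned to the target on the inlet, and zero diffusive flux
through walls.  `V±` is a precomputed "healthy" flow field.  In
unidirectional mode (unipolar MTs) the minus quantities are dropped: 4
unknown field groups (`n0, n+, v+, f+`); bidirectional mode (needed for
MT swirls) carries 7.

Default parameters: `D± = 0.1 µm²/s`, `k± = 1/s`, `k'± = 0.1/s`,
`l± = 1`, `μ = 0.1`, `λ_i = λ_o = 2`, `n_i = 1`, `n_o = 0 mol/µm²`,
`α = β = 1`.  The Stokes–Einstein utility documents the provenance of the
diffusivity scale (0.44 µm²/s for a 1 µm sphere in water; reduced to
0.1 in cytoplasm).  The momentum equation is treated in the
nondimensional form in which it is posed; its `−∇n±` forcing is not
dimensionally reconciled against a physical momentum balance, and no
wall condition is imposed on `v±` (so small advective wall fluxes exist —
see *Conservation*, below).

## Geometry and discretization

Skeletons follow SWC semantics (id, type, x, y, z→dropped, radius,
parent); the root is the inlet and every leaf an outlet.  Cleaning merges
vertices within a tolerance (default 1e-6 µm, lowest id survives) and
collapses degenerate edges.  Synthetic generators produce pipes,
Y-bifurcations, recursive trees, and pipes with a local swelling whose
radius follows `r(s) = r0 (1 + (A−1) bump(s))` with a C1 cubic-smoothstep
bump — the same smoothstep used for every smooth region blend.

Each unbranched chain is swept into two structured half-tube patches
(cross-sections of width `2 r(s)` perpendicular to the centerline, split
along the axis).  At a junction, every incident branch is trimmed back by
a distance `δ ≥ r` chosen from the local angular gaps, and the gap is
tiled by two quad patches per incident branch which meet at the junction
node, at the section midpoints, and at the midpoints of circular wall
arcs.  This template is conforming (every interior edge shared by exactly
two elements), mirror-symmetric for symmetric bifurcations, and keeps
weak conservation exact at junctions.  Junction gaps ≥ 176° are rejected
(near-straight "junctions" should be modeled as chain nodes).

Fields live in tensor-product B-spline spaces (degree 2 by default, C1
inside patches, glued C0 across patch interfaces by geometric
identification of Greville anchors; only patch-boundary dofs are ever
merged).  Element geometry is piecewise bilinear from the control mesh
with 3×3 Gauss quadrature on the bi-unit reference square.  The split
into half-tube patches makes every interface trace space match exactly,
so interpolated fields are continuous to machine precision across
junctions (verified in the tests).

The target velocity solves steady incompressible Navier–Stokes with a
parabolic inlet (peak 1 µm/s by default — the order of motor speeds),
no-slip walls and traction-free outlets, using a stable spline
Taylor–Hood-type pair (quadratic velocity, linear pressure on the same
mesh) and Newton from the Stokes solution.  On a straight pipe the
discrete solution is plane Poiseuille to machine precision, and inlet/
outlet flux balances to ~1e-13 on trees.

SUPG streamline stabilization is applied to the advective equations with
the *target* velocity (not the current iterate) in both the test
direction and τ.  This is a deliberate design choice: it keeps the
discrete constraints exactly quadratic in the unknowns, so the assembled
Newton matrix (objective Hessian + constraint curvature `pᵀ∂²B`) is the
exact Hessian of the Lagrangian, and the outer iteration converges
quadratically.  A consequence worth knowing: at fixed adjoint the
Lagrangian is exactly quadratic in (state, control), so central-difference
gradient checks are exact to roundoff there; the O(ε²) FD regime is only
visible along joint state–adjoint directions.

## The all-at-once solve

The discrete Lagrangian `L = J + pᵀB` yields the KKT system

    ∂L/∂state = J_s + B_sᵀ p = 0,   ∂L/∂control = βMf + B_fᵀ p = 0,
    ∂L/∂adjoint = B = 0,

with Dirichlet dofs eliminated symmetrically.  Newton steps solve the
saddle-point linearization with right-preconditioned GMRES; the default
preconditioner is an incomplete LU of the assembled KKT matrix (a
block-triangular variant — state/adjoint saddle ILU with a lumped-mass
control block — and an unpreconditioned mode are selectable).  A step
whose true linear residual exceeds 1e-8 falls back to a direct sparse
factorization, which at desk scale costs little.  Globalization is a
backtracking line search on the KKT residual norm, with a primal-dual
Levenberg regularization retry when the Newton direction degenerates
(see *Folds*, below).  The stopping tolerance is ‖∇L‖ ≤ 1e-7; runs that
stop on the iteration cap report `converged=False` rather than raising.
Everything is deterministic for fixed inputs; the solver seed only feeds
(optional) randomized initialization.

Transient runs use backward Euler with uniform steps over `[0, T]`,
solving one KKT system per step warm-started from the previous step
(sequential in time).  A fully coupled space–time KKT system is *not*
assembled — the per-step formulation is documented as an approximation;
the time-summed objective uses step weights `Δt`.

## Steady mode, folds, and why scenarios run transiently

Steady mode (the `ParameterSet` default) drops the time derivatives.  It
is well behaved for the healthy pipe and is used for the convergence
contract, the uniform-balance identity and the gradient checks.  However,
at the default parameter scales the *uncontrolled* steady problem is
genuinely singular territory: the free pool's steady balance
`k n0 = k' l n+` conflicts with the outlet Dirichlet data, boundary
layers of width `D/v ≈ 0.1 µm` are unresolvable at desk scale, and the
`−∇n` forcing destabilizes the velocity (damped Newton, pseudo-transient
continuation and Picard alternation all diverge on it).  Even the
*optimized* steady problem sits near solution-branch folds for strong
jams: continuation in jam depth shows regular interior-peak solutions up
to depth ≈ 0.4–0.5 on the default pipe and a fold beyond (the Newton
direction diverges and the KKT Jacobian becomes singular), and parts of
the `k/k'` sweep behave the same way.

The scenario layer therefore runs transiently, which mirrors how such
simulations are actually produced and regularizes every solve through the
mass term.  The forward-limit verification (β = 1e6 against an
uncontrolled forward solve) also runs transiently for the same reason.

## Study conditions (scenario defaults)

The pathological `l±` configurations have no measured magnitudes, so
their shapes and strengths are package choices, fixed once and exposed
in the configuration:

* **Pipe**: 80 × 4 µm, 20 × 4 elements; jam region [30, 50] µm with a
  smoothstep dip of depth **0.6** and transition width one quarter of the
  region; horizon **T = 20 s in 8 steps** (two detachment times, by which
  the jam is developed).  In this regime the model exhibits the
  expected regulation phenomenology: the jam peak sits inside the reduced-MT region,
  weakening either penalty deepens the jam with β's influence exceeding
  α's, and the peak location is non-decreasing in `k/k'`.
* **Swollen pipe / swirl**: swelling centred at 40 µm, support 20 µm,
  radius doubled; swirl region equal to the swelling support with
  centerline amplification 2 and transverse asymmetry 0.5 (`l+` biased to
  the bottom wall, `l-` to the top — the counter-clockwise convention);
  bidirectional mode, T = 20 s.  The retrograde baseline is `l- = 1`
  everywhere (the documented default density for both directions): a
  vanishing `l-` would make the printed retrograde balance inconsistent
  (`0 = k- n0`) and the KKT system singular.
* **Trees**: synthetic 5- and 10-outlet trees (branch lengths 12–30 µm,
  tapering radii) stand in for real traced morphologies; the jam sits on
  the first limb (20–90 % of its arc), depth 0.7, horizon **T = 100 s in
  15 steps** so transport traverses the tree.  The rerouting signature —
  all outlets downstream of the jam depleted, at least one unaffected
  outlet enriched — is robust in sign; its magnitude at the outlets is
  small (≈1e-5 relative depletion) because once the jam saturates, steady
  throughput largely recovers in this model.

Real SWC files are supported (`TransportOptimizationModel.from_swc`), with
z discarded and a warning; the root must have a single child branch.

## Conservation

The printed advection is in non-conservative form (`v·∇w` with a
compressible control velocity), so a pointwise surface-flux balance does
not close; what the scheme conserves is the weak statement — the volume
advective-minus-reactive exchange equals the weak boundary flux carried
by the constrained rows (partition of unity makes SUPG and diffusion drop
from the row sum).  The test suite verifies this identity against an
independent Monte-Carlo quadrature to 1 % of the gross reactive turnover,
and verifies the flow solve's (genuinely conservative) flux balance to
better than 1e-12.

## Numerical choices and degenerate inputs

* Quadrature: (p+1)² Gauss points per element; bilinear geometry.
* SUPG τ: `1/sqrt((2|V|/h)² + (4D/h²)² + σ² + (2/Δt)²)` per element.
* Duplicate-vertex tolerance 1e-6 µm; anchor-merge tolerance 1e-7 µm.
* Initial iterate: `v = V`, concentrations interpolate the boundary data
  along arc length, `f = p = 0`.
* Odd `n_transverse`, self-intersecting tubes (non-positive Jacobians)
  and junction gaps ≥ 176° raise meshing errors naming the culprit.
* Zero inflow produces an identically zero target; `swirl` without
  bidirectional mode, regions outside their branch, and depth ∉ [0, 1)
  raise configuration errors.
* The centerline profile reports `n0 + n+` (the quantity concentration
  figures plot); the retrograde pool can be added on request but its
  inlet-directed background otherwise buries the swirl twin peaks.
* Vorticity: counter-clockwise rotation has positive scalar curl; the
  overlap score is the fraction of top-decile-concentration area inside
  the positive-curl region of the inspected window.

## Problem sizes

All shipped configurations are desk-scale: 80–440 elements, 150–750
scalar dofs per field, KKT systems up to ≈ 9000 unknowns, solved in
seconds (pipe) to about a minute per tree run on one CPU.  These sizes
were chosen for fast, deterministic verification of the solver contracts
and qualitative phenomenology; they do not resolve the `D/v` boundary
layers of the steady limit (see *Folds*), and mesh-convergence of the
transient objective is verified at the 5 % level, not driven to
asymptotics.

## Limitations

* No adaptive local refinement (hierarchical/truncated spline bases):
  fixed-resolution per-patch tensor splines, C0 at junctions.
* No 3D geometries; no geometry deformation in response to jams.
* The transient all-at-once coupling across time steps is approximated
  sequentially in time.
* The solver reports the stationary point it reaches; with nonlinear
  constraints other local minima may exist and no global search is
  attempted.
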