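# Methods

This note documents the model equations as implemented, the numerical
algorithm, the parameter conventions, and the design decisions taken where
several reasonable choices existed.  It states nothing that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The dermis is modeled as a 2D plane-strain slice (`geometry.DomainSpec`:
−15.96 ≤ Y ≤ 15.96 cm, −0.15 ≤ Z ≤ 0 cm in reference coordinates).  The
symmetry of a long rectangular wound makes all out-of-plane derivatives and
the out-of-plane displacement vanish, so the slice carries the full problem.
Four constituents — fibroblasts N, myofibroblasts M, signaling molecule c,
collagen ρ — obey conservation laws of the form
∂z/∂t + ∇·(z v) = −∇·J_z + R_z with the tissue velocity v, coupled to a
quasi-static force balance −∇·σ = ∇·ψ.  Inertia is neglected (healing
timescales are days; elastic equilibration is effectively instantaneous).

Kinetics (`kinetics.py`): adjusted-logistic division with exponent 1 + p and
crowding factor (1 − κ_F F); signal-enhanced division (Michaelis factor
c/(a_cᴵ + c)); differentiation k_F c N; apoptosis δ_N, δ_M; receptor-
saturated net signal secretion k_c (N + ηM) c/(a_cᴵᴵ + c); signal and
collagen proteolysis by a generic MMP whose level g = Fρ/(1 + a_cᴵᴵᴵ c) is an
algebraic function of its producers (the cells), its substrate (collagen)
and its signal-mediated inhibition; signal-enhanced collagen secretion
(factor 1 + k_ρ^max c/(a_cᴵᵛ + c)).  Every rate decomposes as
production − destruction·z with both parts non-negative; this structure is
load-bearing for the positivity of the solver (see below) and is asserted by
a property test.

Mechanics (`mechanics.py`): compressible neo-Hookean solid with
collagen-dependent Young's modulus E(ρ) = Eᴵ√ρ and Poisson ratio ν = 0.49.
The kinematics are Eulerian: from the displacement gradient ∇u (current
coordinates) the Almansi strain e and B = (I − 2e)⁻¹ are formed; the
constitutive law is stated for Jσ and the solver works with σ itself because
the force balance is stated in σ.  Under plane strain the out-of-plane
stretch is one, so J = √det(B₂ₓ₂); the out-of-plane normal stress is
computed but does no work.  The myofibroblast traction enters as an
isotropic stress ψ = ξ M ρ/(R² + ρ²) I; its divergence is never formed
explicitly — the weak form carries ∫ψ:∇φ plus the boundary term ∮(ψn)·φ that
integration by parts produces, which is the consistent treatment of a body
force given as a stress divergence.

Boundary conditions (`geometry.boundary_data`): constituents are pinned at
their unwounded equilibria on the lateral edges and satisfy natural zero-flux
conditions at the subcutaneous and epidermal interfaces; collagen has no
flux term and therefore no boundary condition.  Mechanically, the
subcutaneous interface carries a spring traction −s₁ρu_z in z, the lateral
edges −s₂ρu_y in y, and the epidermal surface is traction-free.  The springs
are evaluated on the *deformed* boundary with ρ interpolated pointwise,
matching the literal reading of the Robin conditions ("proportional to the
collagen concentration and the displacement"); whether reference or deformed
area elements are intended is not decidable from the problem statement, and
the deformed choice keeps the boundary terms consistent with the rest of the
Eulerian assembly.

Two constants are necessary consequences of the others
(`parameters.derive_p`, `derive_k_rho`): p solves
r_F (1 − κ_F N̄) N̄^p = δ_N (p ≈ −0.415 with the defaults, printed as −0.42
at two digits) and k_ρ = δ_ρ ρ̄² (6×10⁻⁸ g/(cells·day)).  Both are recomputed
at construction; a warning fires if they drift more than 2% from the
two-digit reference values (the tabulated values are rounded).

## Non-dimensionalization

`parameters.ScaleSet` defines characteristic scales L* = 1 cm, T* = 1 day,
N* = N̄, c* = c_w, ρ* = ρ̄, σ* = Eᴵ√ρ̄.  The governing equations are
invariant under this rescaling, so the only meaningful correctness statement
is the round-trip identity nondimensionalize → redimensionalize = id, which
is tested to 10⁻¹² including randomized scales.  The solver itself computes
in dimensional cm/g/cells/day units — numerically equivalent to the unit
length/time scales above, with each constituent's linear system scaling
homogeneously in its field units — so no separate dimensionless code path
exists to drift out of sync.

## Mesh

`mesh.generate_mesh` is a force-equilibrium generator in the Persson–Strang
(DistMesh) family.  Points start on an equilateral-row layout whose row and
column spacings are snapped so that integer numbers of rows/columns span the
slice (≥ 4 element rows through the 0.15 cm thickness at the working edge
length 3.46×10⁻² cm); every Delaunay edge then acts as a bar with repulsive
force max(L₀ − L, 0), points are relaxed with pseudo-time step 0.2,
projected back onto the rectangle, and re-triangulated whenever they move
more than 0.1·h.  The generator is deterministic; a seed controls optional
symmetry-breaking jitter (disabled by default).  Triangle quality is
α = 2√3 ‖CA×CB‖ / (‖CA‖² + ‖AB‖² + ‖BC‖²) ∈ [0, 1] (1 iff equilateral,
0 iff collinear, similarity-invariant).  The generated meshes reach
min α ≈ 0.86 at the working resolution, with only the triangles adjacent to
the lateral edges not equilateral.  During the simulation the mesh is
Lagrangian: nodes carry the material displacement, `move_mesh` stores the
grid velocity and treats an inverting element as a time-step rejection
signal; no remeshing is attempted (the simulated deformations do not require
it, and rejection keeps the failure mode explicit).

## Discretization and time stepping

Linear triangular elements for all fields.  Interior integrals use the
second-order Newton–Cotes (vertex) rule — exact for the products of P1
functions with element constants that appear in the assembled forms — and
boundary integrals the two-point Gauss rule (exact through cubics); both
exactness statements are tested.  Because the grid moves with the tissue,
the advective term ∇·(z v) is absorbed into the old/new mass matrices of
the backward-Euler step (the discrete Reynolds transport identity), and the
only discretized fluxes are dispersal/chemotaxis.  Chemotaxis uses the
group finite-element divergence form with the nodal signal gradient
recovered by lumped L2 projection of the element gradients (exact for
globally linear fields; near-second-order interior accuracy is verified by
a refinement study).

Positivity (`fct.py`): the Galerkin transport operator K is upwinded
algebraically (d_ij = max(0, −k_ij, −k_ji)) to a low-order operator whose
backward-Euler step is positivity-preserving; reactions enter via Patankar
splitting (production explicit, destruction as an implicit diagonal), so
non-negativity holds for any step size.  The antidiffusive fluxes
f_ij = m_ij(ż_i − ż_j) + d_ij(z_i − z_j), prelimited against profile
steepening, are then added with Zalesak coefficients computed from stencil
bounds of the low-order and previous solutions: no new extrema, coefficients
in [0, 1], and no limiting of smooth interior profiles.  The production
limiter is cross-checked edge-for-edge against an independently coded
loop-based reference limiter.  The limiter is applied uniformly to N, M and
c (c has only linear diffusion and would rarely activate it, but a uniform
treatment keeps one code path); ρ has no spatial operator and uses the
pointwise mass-weighted Patankar update.

Coupling: each time step iterates (constituents on the current mesh guess) →
(finite-strain mechanics from the updated M, ρ) → (mesh guess moved to the
new displaced configuration) until the scaled inter-iterate differences of
all fields and coordinates fall below tol_fp = 10⁻⁶; the converged limit is
the fully implicit backward-Euler step of the coupled system.  Linear-solve
relative residuals are logged and bounded by 10⁻⁶.  Defaults (tol_fp,
tol_residual = 10⁻⁶, tol_mech = 10⁻⁸, ≤ 50 iterations) are engineering
choices — the convergence thresholds are stated only qualitatively in the
source material — and all are configurable via `SolverOptions`.

Mechanics solve: damped Newton on the finite-strain residual with an
element/edge-wise consistent tangent obtained by central finite differences
(step 10⁻⁶ cm) of the fused residual kernels; the tangent factorization is
reused across iterations and steps (chord method) and reassembled whenever
the observed contraction degrades.  Convergence is declared when the
residual norm falls below tol_mech times a reference force, the larger of
the traction-load norm and a stiffness-scale floor E_max·√(area); the floor
keeps the criterion meaningful as the healing wound's traction load decays
toward zero, where a purely load-relative criterion would chase roundoff.
It resolves displacements to well below 10⁻⁹ cm on the meshes used here.
On Newton failure the traction is applied in increments (load stepping);
persistent failure rejects the time step.  With M ≡ 0 the solver returns
u = 0 exactly.  The hot-path stress kernel is pinned against the public
`mechanics.cauchy_stress` implementation by a property test.

Step-size control: the local truncation error is estimated from the
difference between the backward-Euler solution and the two-step linear
predictor, est = Δtₙ/(Δtₙ + Δtₙ₋₁)·‖z_BE − z_pred‖ in a per-field scaled
max norm (scales N̄, N̄, c_w, ρ̄; coordinates in cm).  Steps are accepted
when est ≤ 10⁻³ and the next step is Δt·clip(0.9·√(tol/est), 0.1, 2.0),
clamped to [10⁻⁸, 5] days (exponent ½ for a first-order method with an
extrapolated error estimate).  Accepted constituent fields are refined by
subtracting the leading error term (local extrapolation); the correction is
capped at zero from below so the positivity guarantee survives the accuracy
boost.  Displacement is not extrapolated — the mechanics is quasi-static
and recomputed exactly each step.  The first step has no history and is
taken at the small initial Δt without an estimate.

## Scenarios and derived quantities

`initial_state` builds the standard wound: a smoothed-Heaviside footprint
w(Y) (steepness cᴵ = 2 cm, half-width cᴵᴵ ∈ [3, 5] cm) with
N = (N_w + (1−N_w)w)N̄, ρ = (ρ_w + (1−ρ_w)w)ρ̄, c = (1−w)c_w, M = 0 and
hence u = 0.  These initial conditions idealize the state at the onset of
the proliferative phase: a uniform-depth rectangular wound, no residual
inflammation dynamics, a single generic growth factor, and none of the
patient-to-patient variability of clinical scar data — so agreement of the
test suite with the model's expected behavior validates the algorithm and
the implementation, not the model's clinical fidelity.

Runs can be checkpointed (`solver.save_checkpoint`/`load_checkpoint`: mesh +
fields to `.npz`) and resumed; a restart resets only the adaptive-step
history, so resumed trajectories differ from uninterrupted ones by the
time-discretization error alone (tested at the 1% level over a short run).

Derived outputs (`postprocess.py`): dermal thickness at y = 0 by linear
interpolation along the deformed epidermal and subcutaneous boundary edges;
material-point traces by barycentric interpolation in the reference element
containing the tracked point (default (0, −0.075) cm — wound centre,
mid-depth — configurable since only an approximate location is prescribed);
per-element strain energy density W.  Scenario presets mirror the studied
parameter grid: δ_M = 6×10⁻² /day ("high apoptosis", normal-scar regime),
δ_M = 2×10⁻³ /day ("low apoptosis", hypertrophic regime), wound half-widths
3/4/5 cm, and an unwounded control.

## Problem sizes used by the tests

The long-horizon regression tests run both apoptosis presets for 400
simulated days on a coarse mesh (mean edge 0.1 cm, ≈ 960 nodes, two element
rows through the thickness) — the package's chosen coarse study resolution,
at which each run takes on the order of a minute.  The mesh-refinement
consistency check repeats a 20-day wound run at mean edges 0.1/0.07/0.05 cm
and requires 2% agreement of the tracked observables.  The full working
resolution (3.46×10⁻² cm, ≈ 9200 triangles) is exercised by the mesh-quality
checks and the acceptance script; the equilibrium-preservation run uses the
5.77×10⁻² cm mesh.

## Numerical choices, degenerate inputs, tie-breaks

* Reaction operations reject negative inputs outright; the solver never
  produces them (FCT + Patankar), and a `max(z, 0)` guard appears only as a
  roundoff clamp after the linear solves.
* Collinear/coincident triangle vertices give quality 0, not an error;
  degenerate slivers from collinear boundary points are dropped during
  Delaunay post-processing.
* Dirichlet rows are imposed exactly (identity rows); antidiffusive fluxes
  into Dirichlet nodes are frozen so limiting cannot perturb pinned values.
* The traction saturation ψ(ρ) peaks at ρ = R with value ξM/(2R); both
  branches are covered by tests.
* A symbol collision between the wound profile and the out-of-plane
  displacement is avoided by naming (`wound_profile` vs `disp_z`); the
  half-maximum constant of the collagen secretion enhancement is treated as
  the single constant a_cᴵᵛ.

## Known limitations

* With the default parameter set the signaling molecule transiently *grows*
  in the wound (net secretion exceeds MMP-mediated decay until collagen
  recovers to ρ ≈ 0.3 g/cm³), driving a large myofibroblast transient in
  both apoptosis regimes; the post-pulse decay, not the peak, is what the
  apoptosis rate controls most strongly at this parameter set.  Relaxation
  back to homeostasis then takes time constants of ≈ 120 days (N) and
  ≈ 83 days (ρ), so at day 400 the tracked fibroblast density and collagen
  concentration are still ≈ 11% and ≈ 15% from their equilibria.  This is a
  property of the kinetics themselves: an independent well-mixed ODE
  integration of the reaction system (scipy, no finite elements) reproduces
  the simulator's tracked-point values to < 0.5%.
* P1 displacement elements at ν = 0.49 are prone to volumetric locking; the
  original algorithm's element choice is reproduced deliberately, so
  absolute deformation magnitudes carry that discretization bias.
* No anisotropic fiber orientation, viscoelasticity, plasticity or
  morphoelastic permanent deformation: contractures cannot form, and every
  simulation ultimately returns to the homogeneous unwounded state.
* No epidermal mechanics, 3D wound geometry, or statistical comparison with
  clinical thickness data.
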