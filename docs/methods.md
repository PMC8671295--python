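# Methods

## Model

Blood flow in the cerebral microcirculation is described by `n = 3`
coexisting porous compartments (arterioles, capillaries, venules) on a
shared domain.  Each compartment carries a volume-averaged Darcy pressure
`p_i` obeying

    ∇·(K_i ∇p_i) = Σ_j β_ij (p_i − p_j) − S_i .

The model is steady, linear and purely resistive: no vessel compliance,
pulsatility or autoregulation.  Sources `S_i` are zero except in
verification problems.  The coupling matrix β is symmetric with zero
diagonal; β₁₃ = 0 by default — pre- and post-capillary vessels are lumped
into β₁₂ and β₂₃, and there is no direct arteriole–venule shunt.  Grey
matter couplings exceed white matter couplings by the fixed ratio βᴳ/βᵂ;
permeabilities are tissue-independent.

Arteriole and venule permeabilities are rank-1 tensors `k_i ζζᵀ` along the
local descending-vessel axis ζ; the capillary permeability is isotropic.
ζ is the normalised negative gradient of a harmonic potential (Dirichlet 1
on the pial surface, 0 on the ventricular surface, zero flux elsewhere),
computed per cell from the P1 solution.  For a rank-1 reference tensor the
full frame rotation `R K R ᵀ` and the outer-product form coincide, which is
why the latter is used.

### Units

Internal unit system: mm–Pa–s.  Tabulated permeabilities in mm³ s kg⁻¹ are
multiplied by 10⁻³ to give mm² Pa⁻¹ s⁻¹ (with lengths in mm,
1 Pa = 10³ kg mm⁻¹ s⁻²), so that both `∇·(K∇p)` and `βΔp` are rates in s⁻¹.
This conversion puts the arteriole penetration length `√(k₁/β₁₂) ≈ 30 mm`
on the scale of the cortical-column thickness (≈ 21.5 mm) — the regime in
which the grey/white perfusion split is non-trivial.  Fixed constants:
1 mmHg = 133.322 Pa; 1 s⁻¹ of volumetric exchange = 6000 ml/min/100 ml.
Pressures are reported relative to the venous outlet.

### Reference parameters

| symbol | value | unit |
|---|---|---|
| k₁ | 1.2344 | mm³ s kg⁻¹ |
| k₂ | 4.28 × 10⁻⁴ | mm³ s kg⁻¹ |
| k₃/k₁ | 2 | – |
| β₁₂ᴳ | 1.326 × 10⁻⁶ | Pa⁻¹ s⁻¹ |
| β₂₃ᴳ | 4.641 × 10⁻⁶ | Pa⁻¹ s⁻¹ |
| βᴳ/βᵂ | 2.538 | – |
| CPP | 75 | mmHg |

## 3D finite elements

Continuous Bubnov–Galerkin discretisation with P1 or P2 Lagrange elements
on tetrahedra.  Coefficients (K, β) are piecewise constant per cell.
Structured box meshes use the Kuhn six-tetrahedra subdivision with a single
consistent diagonal, giving `(n+1)³` P1 and `(2n+1)³` P2 scalar nodes on an
`n³`-cube lattice.  Uniform refinement is Bey's red octasection, with cell
and facet labels inherited by children.

Numerical choices:

* **Quadrature**: Stroud conical products (Gauss–Jacobi) on tetrahedra and
  triangles.  Stiffness/coupling terms use rules exact to degree `2·order`;
  error norms and polynomial loads use a degree-10 rule — the manufactured
  solutions are degree-12 polynomials, and the residual quadrature error is
  orders of magnitude below the discretisation error at every tested
  resolution (checked against a finer rule).
* **Dirichlet conditions** are enforced by symmetric elimination, so the
  reduced operator stays symmetric positive definite and boundary values
  are exact.
* **Periodic conditions** identify DoFs across translated box faces by
  canonical-coordinate hashing (tolerance 10⁻¹⁰); paired values are equal
  bitwise because they share one unknown.
* **Linear solvers**: SuperLU with symmetric-mode minimum-degree ordering
  (`direct`), or conjugate gradients preconditioned by the exact
  factorisation of each per-compartment diagonal block (`iterative`).  The
  block preconditioner exploits that compartments only couple through mass
  (reaction) terms; on the verification problems CG converges in a few tens
  of iterations, and the two paths agree to 10⁻⁸ relative.  The convergence
  driver switches to the iterative path above ~5 × 10⁴ unknowns, where the
  coupled factorisation becomes memory-bound.
* **Rank-1 permeabilities** are accepted as-is: the coupling terms render
  the coupled operator nonsingular even though a single compartment's
  stiffness alone is semi-definite.

### Manufactured-solution verification

Exact pressures `p₁ = f(x)f(y)z²`, `p₂ = f(x)f(y)f(z)`, `p₃ = −p₁` with
`f(t) = 16t²(1−t)²` on the unit cube; sources derived symbolically (sympy)
so the strong-form residual of the exact fields is zero to round-off —
asserted at random points as an independent oracle.  Boundary conditions:
periodic lateral faces, exact Dirichlet traces on z = 1 for compartments 1
and 3, homogeneous Neumann elsewhere (the capillary compartment is anchored
through coupling).

The case's constants live in `src/poroperf/data/manufactured_case.yaml`
(configuration, not code): K₁ = diag(0,0,1), K₂ = I, K₃ = diag(0,0,2),
β₁₂ = 10, β₂₃ = 20.  They mirror the physiological structure — rank-1
descending-vessel tensors with the venule twice as permeable, isotropic
capillaries — at O(1) scale so no term dominates.  With these constants the
study reproduces the reference verification levels (e.g. aggregated L2
error 0.0286 at P1/n=8, 0.0140 at P2/n=4, boundary gradient probe 2.006 at
P2/n=8 against the exact value 2); the L2 norm aggregates the three
compartments root-sum-square.  The gradient probe at the boundary point
(0.5, 0.5, 1) evaluates the one-sided FE gradient in a containing cell.

Problem sizes in the default study: P1 over n_edge = 2…32 (up to 107,811
coupled unknowns) and P2 over n_edge = 2…16 (same size); the finest-P2 row
(~2.5 M unknowns) is outside the study's envelope and is omitted.

## 1D tissue column

With homogeneous scalar permeabilities the system reduces per layer to
`k_i p_i'' = Σ_j β_ij (p_i − p_j)`.  Writing `r = [p; q]`, `q = p'`, gives
`r' = A r` with `A = [[0, I], [B, 0]]`, `B = diag(α e) − α`,
`α_ij = β_ij / k_i`.  `B` annihilates the constant vector by construction,
so `A` has a defective zero eigenvalue; the exponential eigen-expansion is
completed with constant and linear-in-x polynomial modes (two per connected
coupling block), without which the boundary-condition system would be
rank-deficient.  For symmetric β and positive k, `B` is similar to a
symmetric positive-semidefinite matrix, so all eigenvalues are real and
non-negative; complex pairs would indicate non-physical input and are
rejected.

Numerical conditioning: each exponential mode is anchored at its nearer
subdomain end, `exp(−√μ · distance)`, so all basis functions are bounded by
one even when the coupling is stiff (the capillary rates give
`√μ ≈ 3.7 mm⁻¹` over a 21.5 mm column, i.e. raw exponentials of order
e⁸⁰).  The boundary-condition system of the reference problem then has
condition number ~10³; ill-conditioning beyond 10¹² triggers a warning.

Boundary conditions (pial end x = 0, ventricular end x = l): p₁(0) = CPP,
p₃(0) = 0, q₂(0) = 0, and q_i(l) = 0 for all compartments.  The capillary
pial condition is not uniquely dictated by the 3D analogy; zero capillary
flux (the pial-surface analogue of the 3D capillary condition) is adopted.
Layer and whole-column averages of pressure and perfusion use closed-form
antiderivatives of the modal expansion — no quadrature.

An independent P1/P2 Galerkin solver on the layered interval provides the
numerical cross-check (agreement < 1% of CPP at 100 P1 elements,
second-order convergence) and is exactly the engine a stiff parameter scan
would fall back to.

With the reference parameters and layer thicknesses 13.55 mm (grey) +
7.99 mm (white), the column yields volume-averaged perfusion 43.0 (whole),
56.3 (grey) and 20.6 (white) ml/min/100 ml.

## Post-processing

Darcy velocity `u_i = −K_i ∇p_i` is available cell-wise at its natural
order (dP0 for P1, dP1 for P2) or L2-projected onto continuous P1/P2 via a
global mass-matrix solve.  Surface flow `Q^Γ = −∫ u₁·n dΓ` (inflow
positive) uses facet quadrature with outward normals; volumetric flow
`Q^Ω = ∫ β₁₂(p₁−p₂) dΩ` uses exact elementwise quadrature.  Because the H1
discretisation is not conservative, `Δ_r = (Q^Γ − Q^Ω)/Q^Ω · 100%` is the
mass-conservation diagnostic; on the layered-box fixture `Q^Γ` always
underestimates, and |Δ_r| falls monotonically with refinement and with
element order while `Q^Ω` moves by < 1% — so `Q^Ω` is the robust flow
estimate and higher-order elements are what boundary-flux accuracy buys.

Occlusion of a feeding artery replaces the arteriole Dirichlet condition on
the affected pial territory with zero flux; the venule condition on the
same patch is kept (venous drainage is not blocked by an arterial clot).
Occluding every inlet is rejected as ill-posed.  Infarcted tissue is the
volume fraction of cells whose cell-averaged perfusion drops by strictly
more than 70% against the healthy baseline; the classification is computed
on the fractional drop so that exactly-at-threshold cells stay healthy
independent of floating-point representation.  A uniform-velocity inlet
(`b = Q/area`) and field statistics (min/max/mean of p₁ and F) are provided
for inlet-condition comparisons.

## Calibration

The two layer thicknesses are fitted to perfusion targets (whole, grey,
white) by bounded least squares on the *unweighted absolute* misfit in
ml/min/100 ml.  All three targets share one unit and scale, so no weighting
is warranted; and since the whole-column average is the length-weighted
mean of the other two, two parameters can drive the misfit of consistent
targets to zero.  A relative-misfit cost was considered and rejected: with
integer-rounded targets it drags the optimum several percent away from the
generating geometry, whereas the absolute cost recovers it to 0.1%
(self-consistency is tested by regenerating targets from a known geometry).
Infeasible targets (e.g. grey below white perfusion under a grey-dominant
coupling ratio) leave a positive residual and a warning — never a silent
success.

## Sensitivity analysis

One parameter at a time is scaled over [0.1, 10] × baseline — valid as a
global picture because the system is linear in pressure and monotone in its
conductances.  The default grid is 101 linear samples with the baseline
point guaranteed present (appended when the raw grid misses scale 1.0
exactly).  Elasticities are central differences of
`(Δoutput/output)/(Δscale/scale)` at scale 1.  The 1D analytic column is
the fast engine (a 101-point scan takes well under a second); the 3D
cross-check is a two-layer box (10 × 10 × 21.54 mm, grey next to the pial
face) with rank-1 descending permeabilities and half of the pial face
occludable, which reproduces the healthy/occluded/infarct structure of an
organ-scale scan.  Geometry scaling multiplies all lengths by the cube root
of the volume factor.

Expected and verified behaviour: CPP elasticity of perfusion is exactly 1
(hydraulic Ohm's law); the infarct fraction is exactly CPP-invariant (it
thresholds a ratio of two fields that scale together); perfusion is
non-decreasing in every conductance; capillary and venous permeability
elasticities are small against the coupling-coefficient elasticities (flow
"avoids" the high-resistance capillary bed, so the couplings carry most of
the resistance); 1D and 3D elasticity rank orders agree.

## What the synthetic fixtures do and do not show

The unit cube, layered box and column are structured, label-clean
geometries with exactly matching periodic faces and axis-aligned
orientation fields.  They exercise the discretisation, constraint handling,
conservation diagnostics and parameter logic — not surface extraction,
mesh quality, perfusion-territory labelling or curvature effects of a
patient geometry.  Passing tests therefore demonstrate solver correctness
and the internal consistency of the 1D/3D model pair, not anatomical
fidelity; organ-scale flow-rate tables require a patient mesh and are out
of scope.

## Known limitations

* Steady, linear, purely resistive: no autoregulation, compliance or
  pulsatility; no time dependence.
* Three compartments with spatially uniform couplings per tissue class;
  arterioles feeding deep tissue directly are not representable, so
  isolated periventricular infarcts cannot appear.
* H1 (pressure) discretisation is non-conservative; boundary-flux estimates
  need P2 elements or refinement (quantified by the Δ_r diagnostic).
* Mesh I/O covers Gmsh MSH 2.2 ASCII and inline-ASCII VTU; binary/appended
  VTU and MSH 4.x are not read.
* The 1D column is planar; curvature (cylindrical/spherical) variants are
  not implemented, which limits its fidelity under geometric scaling.
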