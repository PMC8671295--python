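# poroperf

Multi-compartment porous (Darcy) modelling of cerebral perfusion: a verified
3D finite-element solver, an analytical 1D tissue-column model, flux and
perfusion post-processing with infarct estimation, column calibration, and
one-at-a-time sensitivity analysis.

## Who this is for

Organ-scale haemodynamic modellers who treat the cerebral microcirculation as
coexisting porous continua — arterioles, capillaries and venules sharing the
same spatial domain — and need a transparent, verifiable reference
implementation: solver verification against manufactured and analytical
solutions, mass-conservation diagnostics for boundary-flux estimates, and a
fast 1D surrogate for parameter studies that would be prohibitively expensive
in 3D.

## The model

The steady Darcy pressure `p_i` of compartment `i` (1 = arterioles,
2 = capillaries, 3 = venules) obeys the coupled system

```
∇·(K_i ∇p_i) = Σ_j β_ij (p_i − p_j) − S_i,
```

where `K_i` is the compartment permeability tensor (rank-1 along the
descending-vessel axis for arterioles/venules, isotropic for capillaries),
`β_ij` the inter-compartment coupling conductance, and `S_i` a volumetric
source.  Boundary conditions mirror the brain: arteriole pressure CPP and
venule pressure 0 on the pial surface, zero capillary flux there, and zero
flux of everything through the ventricular surface.  Perfusion is
`F = β₁₂ (p₁ − p₂)`, reported clinically in ml/min per 100 ml of tissue.

The package has two engines:

* **3D**: P1/P2 Lagrange finite elements on tetrahedra (structured Kuhn
  meshes of boxes, or any labelled MSH 2.2 / VTU mesh), with periodic,
  Dirichlet and Neumann conditions, verified by the method of manufactured
  solutions on the unit cube.
* **1D**: the grey+white tissue column solved *analytically* by an
  eigen-modal expansion of the companion system `r' = A r`,
  `A = [[0, I], [B, 0]]`, `B = diag(α e) − α`, `α_ij = β_ij / k_i`,
  completed with polynomial modes for the defective zero eigenvalue and
  cross-checked by an independent 1D Galerkin solve.

## Worked example

The reference parameter set (permeabilities in mm³ s kg⁻¹, couplings in
Pa⁻¹ s⁻¹: k₁ = 1.2344, k₂ = 4.28e-4, k₃/k₁ = 2, β₁₂ᴳ = 1.326e-6,
β₂₃ᴳ = 4.641e-6, βᴳ/βᵂ = 2.538, CPP = 75 mmHg) on a 13.55 mm grey +
7.99 mm white column:

```
$ poroperf column
<F>  = 43.02 ml/min/100ml
<F>G = 56.25 ml/min/100ml
<F>W = 20.58 ml/min/100ml
```

Whole-column perfusion is 43 ml/min/100 ml — a physiologically sensible
cerebral value — split into well-perfused grey matter (56) and less-perfused
white matter (21).  The inverse problem recovers the column geometry from
those targets:

```
$ poroperf calibrate
l_G = 13.551 mm
l_W = 7.985 mm
residual = 0.49 ml/min/100ml
```

The residual is the root-sum-square misfit against the integer-rounded
targets; it cannot reach zero because the targets are rounded.

Other commands: `poroperf cube-verify` (manufactured-solution convergence
table), `poroperf sensitivity --param cpp --n 101 --out curve.csv`
(one-at-a-time scans; the CPP elasticity of perfusion is exactly 1 — the
hydraulic Ohm's law), `poroperf solve-mesh`, `poroperf flux`,
`poroperf fixture`.

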