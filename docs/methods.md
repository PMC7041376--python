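# Methods

## Model overview

The package couples four models around one design loop:

1. a **parametric lattice geometry**: cylindrical strands of diameter *D*
   laid in layers with in-layer spacing *d_fil*, consecutive layers rotated
   90°, interpenetrating vertically by `overlap_fraction · D` (default 0.1),
   so the layer pitch is `(1 − overlap) · D`;
2. **Biot poroelasticity** for the composite of stiff polymer strands and
   soft granulation tissue filling the pores, both treated as saturated
   porous media;
3. the **Prendergast–Huiskes mechanoregulation rule** mapping the local
   mechanical environment of the pore tissue to a differentiation phenotype;
4. a **bounded scalar optimization** of *d_fil* maximizing the predicted
   mature-bone volume fraction BO%.

Around the loop sit the FDM process math (nozzle / flow rate / slice height
needed to actually print a strand of diameter *D*) and synthetic metrology
(the statistics used to compare a printed scaffold with its nominal design).

## Computational domain

The full part is a cylinder (R = 20 mm, h = 5 mm), far too large to mesh at
strand resolution on a desktop. Because the lattice interior is periodic and
the loading (uniform plate compression) preserves its mirror symmetries, the
mechanics is solved on a rectangular periodic sub-volume with symmetry faces:
by default **half a d_fil period in x and y** — the minimal symmetric cell,
with strand axes on two faces and the pore center at the opposite corner —
and a stack of `n_layers` (default 10) strand layers in z. A full-period
cell is available (`in_plane="full"`) and yields the same volume fractions
and fields; the half cell costs a quarter as much. The curved outer boundary
and the finite cylinder edge are not modeled; results represent the periodic
interior.

Voxelization labels a voxel *scaffold* when its center lies inside any
strand cylinder, else *granulation*. The voxel edge snaps so the in-plane
extent is a whole number of voxels; a resolution coarser than D/4 is
rejected. Total volume bookkeeping (V_TOT, porosity, BO%) refers to this
modeled sub-volume.

## Poroelastic solver

* **Unknowns**: solid displacement and pore pressure, trilinear (Q1/Q1) on
  voxel hexahedra. Equal-order pressure interpolation is stabilized with a
  Brezzi–Pitkäranta pressure Laplacian, τ = h²/(4(λ+2G)) per element and
  phase, applied to the pressure increment so steady states are untouched.
* **Constitutive constants** per phase: E, ν, permeability k (supplied as
  hydraulic mobility in m⁴ N⁻¹ s⁻¹, converted ×10¹² to mm⁴ N⁻¹ s⁻¹), grain
  and fluid bulk moduli giving Biot coefficient α = 1 − K_drained/K_grain
  and storage 1/M = (α − n)/K_grain + n/K_fluid. Defaults: scaffold polymer
  E = 2300 MPa, ν = 0.3, k = 10⁻¹⁴, n = 0.5, K_grain = 13920 MPa,
  K_fluid = 2300 MPa; granulation tissue E = 0.2 MPa, ν = 0.167, k = 10⁻¹⁴,
  n = 0.8, K_grain = K_fluid = 2300 MPa.
* **Boundary conditions**: bottom clamped; lateral faces symmetric (zero
  normal displacement, no flux); loaded top face drained (p = 0) — free
  fluid exchange at the open face, no flux elsewhere; optional drained
  bottom with prescribed pressure for Darcy benchmarks. The rigid
  frictionless plate ties every top-face vertical displacement to a single
  scalar carried as a bordered unknown (a one-rank Schur complement around
  the sparse LU factor) rather than a master–slave reduction, whose dense
  master row destroys the sparse ordering.
* **Loading history**: the total force p × A is ramped linearly over 1 s and
  the stimulus evaluated at t = 1 s, the ~1 Hz physiological loading scale
  customary for this mechanoregulation model; ramp, evaluation time and step
  (default 0.05 s, backward Euler) are configuration knobs. The solver
  accepts arbitrary strictly increasing time grids (the consolidation
  benchmark uses a geometric grid to resolve the early pressure boundary
  layer).
* **Outputs** per element at the centroid: principal strains (eigenvalues of
  the centroid strain tensor) and Darcy flux magnitude |−k ∇p| in µm/s. The
  bottom reaction is checked against the applied force (0.5% tolerance)
  every solve.

Verification (tests): single-element stiffness against an exact symbolic
integration; drained confined compression against ε = −p/(λ+2G) (<1%);
Terzaghi 1-D consolidation pressure profile and settlement against the
series solution (<2% relative L2 at mid-consolidation, 40 elements, 400
geometric time steps); steady Darcy flow against v = kΔp/L (machine
precision); exact load–reaction balance and linearity in p.

## Mechanoregulation

S = γ/a + v/b with a = 0.0375 (γ as a dimensionless fraction; the constant
is usually quoted as 3.75%) and b = 3 µm/s. γ is the octahedral shear
strain (2/3)·√[(ε_I−ε_II)² + (ε_II−ε_III)² + (ε_I−ε_III)²]. Phenotype bins
are half-open, closed on the lower edge — [0, 0.01) resorption, [0.01,
0.53) mature bone, [0.53, 1) immature bone, [1, 3) cartilage, [3, ∞)
fibrous — a total deterministic partition that differs from the open
intervals usually quoted only on the measure-zero breakpoints. Only
granulation elements differentiate; BO% = 100 · V_bone / V_TOT. No time
evolution of tissue replacement is modeled: the stimulus of the initial
granulation state is scored once.

## Optimization

Ω(d_fil) = −BO% is minimized over [D, 1100 µm]. On coarse voxel grids BO%
is piecewise constant in d_fil with plateau noise, so a derivative-free
two-stage scheme is used: an 8-point equispaced pre-scan brackets the
basin, golden-section refines it to a 10 µm tolerance, with an evaluation
budget of 50 and caching on (D, d_fil, p, resolution, layers). On unimodal
responses with a known argmax the scheme recovers the optimum within the
tolerance in ≤ 40 evaluations. A user-supplied tentative start is evaluated
first but never replaces the scan. The factorial campaign runs one
optimization per (D, p) pair and records per-cell failures without aborting.

## FDM process model

Melt volume conservation D_n² v_n = D² v_h with v_n = (f/100) v_h gives
f = 100 (D/D_n)². Slicers take an integer percentage; the value is
truncated toward zero — (700/800)² = 76.5625% prints as 76 — a convention
adopted for all diameters. The nozzle is the smallest available bore ≥ D
(400 or 800 µm by default). Slice height is set equal to the target strand
diameter, the simplest law consistent with reducing it together with D to
keep under-extruded strands nearly circular; defaults v_h = 40 mm/s,
extrusion 180 °C, bed 50 °C.

## Synthetic metrology

The generator draws normal measurements with mean nominal·(1+bias) and a
given SD (seeded), 10 repeats per dimension check and 3 for overlap depth,
emulating CMM repeatability; the real instrument's error law and any
systematic printer artifacts (e.g. the diameter bias of heavily
under-extruded strands) are outside the model, so passing tests validate
the statistics, not the printer. Summary statistics: sample mean, SD with
the n−1 denominator (standard metrology practice; pooling across a
configuration's 3 × 10 repeats happens at the measurement level), percent
deviation |nominal − mean|/nominal·100, and the [mean ± SD] band check. For
a normal model the band contains an independent fresh measurement ≈68% of
the time at large n — the calibration property asserted (±5 points) over
1000 seeded sets.

## Scaled study conditions

Trend-level results use 100 µm voxels (≥4 across every campaign strand
diameter), the 10-layer half-period cell, 1 s ramp in 20 steps: one
objective evaluation costs 0.1–1 s and one optimization cycle ~15–17
evaluations. Under these conditions the campaign reproduces the expected
physics: the optimal spacing is non-increasing in load (collapsing to near
strand contact at 1.5 MPa, the stiffening response that protects the pore
tissue from over-stimulation) and the peak BO% is non-increasing in strand
diameter (finer strands leave more pore volume in the mature-bone band).
Monotonicity is asserted to within one pre-scan step (100 µm) in spacing
and one BO-point in BO%, the observed scale of voxelization noise. Absolute
BO% values and optimal spacings at this resolution are not comparable
element-wise to a full-resolution cylinder model — only the trends are.

## Known limitations

* Linear kinematics and linear constitutive behavior; no contact, creep or
  large strain.
* No tissue evolution in time (single-shot scoring of the granulation
  state); no cell migration or nutrient transport.
* The sub-volume omits the cylinder's curved boundary; edge effects and
  strand termination are not represented.
* Strand cross-sections are perfect circles; inter-layer fusion is modeled
  purely by geometric interpenetration (no fillet material).
* Drainage boundaries and the loading history of the physical experiment
  are not uniquely known; the defaults above are the package's choices and
  are exposed as configuration.
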