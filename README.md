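# scaffopt

Mechanobiology-driven design of FDM-printed strand-lattice scaffolds for bone
tissue engineering.

A bone scaffold printed by fused deposition modeling is a stack of layers of
parallel cylindrical strands (diameter *D*, center-to-center spacing
*d_fil*), consecutive layers rotated by 90° and fused over a small vertical
overlap. After implantation the pores fill with granulation tissue whose
mesenchymal stem cells differentiate according to the mechanical environment.
`scaffopt` asks the design question: **for a given strand diameter and
compressive load, which strand spacing maximizes the volume of pore tissue
predicted to become mature bone?** — and then computes the printer settings
that fabricate the answer.

## What it computes

For each candidate spacing the tool chains:

1. **Geometry** (`scaffopt.geometry`) — voxelizes the periodic strand lattice
   and its pore-filling granulation phase on a regular grid (layer pitch
   `(1 − overlap) · D`, default overlap 0.1 · D).
2. **Poroelasticity** (`scaffopt.fem`) — solves quasi-static Biot
   consolidation of the two-phase domain (Q1/Q1 voxel hexahedra, stabilized
   equal-order pressure, backward Euler) under rigid-plate compression with
   symmetry faces: clamped bottom, drained loaded face, force per unit area
   *p* ramped over 1 s.
3. **Mechanoregulation** (`scaffopt.mechanoreg`) — evaluates the
   Prendergast–Huiskes stimulus per pore element,

   S = γ/a + v/b,  a = 0.0375, b = 3 µm/s,

   with γ the octahedral shear strain and v the interstitial (Darcy) fluid
   speed, bins S into phenotypes (resorption / mature bone / immature bone /
   cartilage / fibrous), and reports BO% = 100 · V_bone / V_total.
4. **Optimization** (`scaffopt.optimize`) — minimizes Ω(d_fil) = −BO% over
   d_fil ∈ [D, 1100 µm] by grid pre-scan plus golden-section refinement, and
   runs the factorial campaign over D ∈ {400…800 µm} × p ∈ {0.2…1.5 MPa}.
5. **Process planning** (`scaffopt.fdm`) — selects the nozzle and flow-rate
   percentage f = ⌊100 (D/D_n)²⌋ (melt continuity D_n² v_n = D² v_h,
   v_n = f · v_h) to print a target strand diameter.
6. **Metrology** (`scaffopt.metrology`) — synthetic CMM-style measurement
   sets and the mean / SD / percent-deviation statistics used to compare a
   fabricated scaffold with its optimized dimensions.

## Worked example

Optimize the spacing for 600 µm strands under 0.5 MPa on the scaled periodic
sub-volume (100 µm voxels, 10 layers):

```text
$ scaffopt opt --D 600 --p 0.5
d_fil_opt = 1083.1 um  BO%_max = 29.280  (15 evaluations, converged=True)
  d_fil    600.0 um -> BO% 13.737
  d_fil    671.4 um -> BO% 20.635
  ...
```

At this gentle load the response is still rising toward the upper spacing
bound: wider pores soften the lattice just enough to lift the pore-tissue
stimulus into the mature-bone band (0.01 ≤ S < 0.53) through most of the
pore volume, so about 29% of the modeled volume is predicted to mineralize.
At the highest campaign load (1.5 MPa) the optimum instead collapses toward
strand contact (d_fil ≈ D), stiffening the scaffold to shield the pores from
over-stimulation — the same qualitative behavior seen when the optimization
is run at full scale.

Print the strands for the companion geometry:

```text
$ scaffopt flowrate --D 500
D_um = 500
D_n_um = 800
flow_rate_percent = 39
v_n_mm_s = 15.6
slice_height_um = 500
...
```

A 500 µm strand from the 800 µm nozzle needs 39% flow
(⌊100·(500/800)²⌋ = 39) and a proportionally reduced head speed and slice
height.

Other entry points: `scaffopt build` (voxelize + STL/VTK export),
`scaffopt campaign` (full D × p table), `scaffopt simulate-measurements` /
`scaffopt report` (synthetic metrology).

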