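# Methods

This note records the modelling assumptions, conventions and numerical
choices behind `jawstrain`, and what the synthetic phantom can and cannot
say about real mandibles.

## Mechanical model

Small-strain, static, isotropic linear elasticity on 4-node (constant
strain) tetrahedra. Constant-strain elements make per-element quantities
unambiguous — every derived field (principal strains, shear components,
differential maps) is a single number per element, which is exactly what
the element-level differencing pipeline needs. The price is slow bending
convergence; the cantilever verification quantifies it (the suite's fixed
80×1×16 mesh is 4.2 % below the Euler–Bernoulli tip deflection, with a
monotone refinement series toward it). Quadratic elements, contact,
geometric/material nonlinearity and time dependence are out of scope.

Interfaces between regions (tooth–PDL, PDL–bone, screw–bone) are bonded by
shared nodes on conforming meshes; no master–slave tie machinery exists,
and the phantom generator guarantees conformity by construction (a single
structured lattice split into 6 Kuhn tetrahedra per cell, which keeps the
face diagonals of neighbouring cells matched).

Constraints are zero-displacement on named node sets, applied by row/column
elimination of the constrained DOFs: satisfaction is exact, the reduced
matrix stays symmetric positive definite, and reactions are recovered
cleanly as `K u − f` on the eliminated rows. The reduced system is solved
with a sparse direct LU factorisation; each solve checks a relative
residual (tolerance 1e-8) and reports the global equilibrium defect
(reactions + applied loads), which is zero to roundoff because rigid
translations span part of the stiffness nullspace.

## Material calibration

Cortical elasticity follows three affine lines — density from grayscale,
then E and ν from density — with the coefficients given in
`CalibrationModel`. Two guards are needed because the printed lines leave
their physical range when extrapolated:

* `E_floor` (default 50 MPa) keeps the stiffness positive where the E(ρ)
  line is negative at low density;
* ν is clamped to [0.05, 0.49] so the isotropic stiffness stays definite.

The density line is implemented as intercept + slope (the conventional
affine calibration form, matching the other two lines); both coefficients
are configurable. Heterogeneity is discretised into `n_bins = 80`
equal-width density bins over the observed range; each element takes its
bin-midpoint properties, so the binning error in E is bounded by one bin
width times the E slope (asserted in the tests). Equal-count binning was
the alternative; equal-width was chosen because it makes that error bound
trivial. Orthotropy is not modelled: only the scalar E/ν lines are
implemented, so the cortical field is heterogeneous-isotropic.

Fixed regions: teeth 24 500 MPa / 0.49, trabecular 10 000 MPa / 0.3, screws
105 000 MPa / 0.36. PDL variants: 0.68 (reference), 0.07, 0.18, 13.8,
1750 MPa, all at ν = 0.49; `NO_PDL` assigns tooth properties to the PDL
region so the comparison stays geometry-matched (same mesh, same loads,
material swap only). Geometric removal of the shell is available as a
separate, explicitly labelled study mode of the generator
(`pdl_thickness = 0`), which produces an identical lattice whose former
shell cells are relabelled cortical.

## Loading

Muscle force magnitude is PCSA × specific tension × normalized EMG with
specific tension 30 N/cm²; the direction runs from the insertion-node
centroid to the cranial attachment point, and the total is split equally
across the insertion nodes (the splitting rule is a package choice; the
total applied load is invariant to it, which is the tested contract —
area-weighted splitting would be the natural extension). Nodal force
components that fall on constrained axes are zeroed with a warning.

Anatomical frame: X superoinferior, Y anteroposterior, Z mediolateral —
the unique assignment under which the sagittal, frontal and transverse
planes are XY, XZ and YZ, so the reported shear components are ε₁₂, ε₁₃,
ε₂₃ in that frame. Condyle constraints act on one node per condyle;
rotation there is automatically free because solid elements carry only
translational DOFs.

## Strain conventions

* Tensor shear (ε_ij = ½(∂u_i/∂x_j + ∂u_j/∂x_i)) is stored everywhere;
  engineering shear γ = 2ε is available through an explicit accessor and
  outputs are labelled. All reported strains are in microstrain.
* "ε₁" is the maximum principal strain; the quantity reported as "ε₂" is
  the *minimum* principal value — the smallest 3D eigenvalue for volume
  elements, the smaller in-plane value at a gauge (rosette gauges are
  two-dimensional; the two conventions are kept distinct in the API as
  `e1` / `e_min`).
* Gauge sites are (center, radius, rotation) triples; patch membership is
  boundary faces whose centroid lies within the radius (a deterministic
  stand-in for manual radiograph overlay). Tensors are rotated into the
  gauge frame (local xy = gauge plane) before the 2D principal analysis.
* In-plane ε₁ orientation: θ = ½·atan2(2ε_xy, ε_xx − ε_yy) measured
  counterclockwise from the gauge local +x, mapped into [0, 360). A strain
  axis is 180°-ambiguous; this fixed convention picks the representative
  returned by the half-angle formula, and the same convention is applied
  to FEM and synthetic in-vivo data so containment comparisons are
  consistent.
* Differential maps difference derived quantities per element, never
  tensors (principals are computed per model first). Region summaries use
  the sample SD (n − 1); a single-element region reports SD 0.

## Validation machinery

Quartiles use linear interpolation between order statistics (the common
boxplot default); whiskers are Q1 − 1.5·IQR and Q3 + 1.5·IQR. A model
passes a gauge/quantity when its FEM median lies inside the whisker
envelope, and more loosely inside the full sample range. Orientation
verdicts are computed on the circle: the smallest arc covering the FEM
orientations must lie inside the smallest arc covering the in-vivo
orientations — a deterministic replacement for a visual polar-histogram
comparison.

## The phantom, and what it does (not) emulate

`PhantomSpec` builds a curved-beam corpus (circular-arc midline, rectangular
cross-section) with two condylar posts, per-side tooth blocks in sockets,
and — at `pdl_thickness ≥ 3` — a conforming PDL shell exactly that many
element layers thick around each root (the 3-layer floor mirrors the
minimum tissue-space thickness that non-manifold meshing of real scans
requires; 0 disables the shell and the layout is held fixed so the twins
share nodes and tets). Defaults: 100 mm arc at 29 mm radius, 12 × 14 mm
cross-section, three teeth per side with the anterior working tooth bitten,
1.25 mm edge length → 56 760 tets. Everything is deterministic given the
spec and seed; an over-coarse edge length raises an error stating the
maximum admissible value.

The bitten-teeth minority matters: in a real mandible only a few of ~16
teeth are occlusally loaded, and the tooth-root strain average is dominated
by free-riding teeth, which strain *more* when the PDL is removed (they
become welded to the corpus) — the constrained tooth behaves oppositely.
The phantom reproduces that ratio qualitatively with one bitten tooth in
six.

The grayscale generator writes a smooth low-order polynomial plus bounded
noise over cortical elements. Its default range (1.6–2.2 × 10⁶ scanner
units) is chosen so the printed calibration yields cortical E of ~13.5–18.5
GPa — the band reported for primate mandibular cortex; at those densities
the printed ν line is far below its physical range and sits at the 0.05
floor, a documented consequence of extrapolating the printed coefficients
(the calibration and clamps are fully configurable). The in-vivo generator
samples a piecewise-linear inverse CDF anchored at the planted min / Q1 /
median / Q3 / max, so empirical quartiles converge to the plant; planted
ranges narrower than the IQR are rejected.

What passing the phantom tests shows: the pipeline's mechanics, bookkeeping
and statistics behave correctly, and the qualitative PDL sensitivity
pattern (stiffer interface → lower surface and shear strains; no ligament →
loaded tooth roots) is a genuine consequence of the modelled physics. What
it does not show: agreement with any real subject's strain magnitudes —
the phantom is not macaque anatomy, the muscle table is a synthetic
stand-in (PCSA/EMG values are plausible, not measured), and the synthetic
in-vivo spreads are planted. Published gauge-site tables from real subjects
are therefore not reproduction targets here.

## Problem sizes and determinism

The test suite uses a minimal conforming phantom (~17.7 k tets) for unit
tests and the full default phantom (56 760 tets, six variants, ~1 minute)
for the end-to-end directional checks; the acceptance script uses the same
sizes. All random draws go through `numpy.random.default_rng` seeded from
the run seed; identical configs give byte-identical CSV and JSON outputs
(floats are serialised via `repr` round-tripping in mesh files and a fixed
`%.10g` format in tables).

## Native JSON mesh format

A single object: `{"format": "jawstrain-mesh", "version": 1, "nodes":
[[x,y,z]...], "tets": [[n0,n1,n2,n3]...], "region": [label per element],
"node_sets": {name: [ids]}, "element_sets": {name: [ids]}}` with 0-based
indices and mm coordinates. The INP subset restores 1-based ids on write.

## Known limitations

* Linear tets under-predict bending deflection at fixed mesh density; all
  cross-variant comparisons use identical meshes, so this biases magnitudes,
  not signs.
* Near-incompressible regions (ν = 0.49 PDL) are prone to volumetric
  locking with linear elements; again absorbed by the matched-mesh design.
* One-node condyle constraints create local singularities; gauge and
  region statistics are taken away from them.
* The orientation-arc containment rule is stricter than a visual range
  comparison when the FEM arc barely overhangs the in-vivo arc.
* No orthotropy, no time dependence, no fibrous PDL microstructure, no
  hyperelastic/viscoelastic/multiphase PDL constitutive behaviour.
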