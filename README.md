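# jawstrain

Finite-element sensitivity analysis of the **periodontal ligament (PDL)** —
the thin compliant tissue anchoring each tooth root in its bony socket — and
its effect on bone strain regimes in the primate mandible during simulated
unilateral chewing.

Large-scale mandible/cranium FE models routinely either omit the PDL or
assign it one of a very wide range of published Young's moduli
(0.07–1750 MPa). `jawstrain` quantifies what those choices do to the strain
field. It is aimed at comparative biomechanists and FE modellers who want a
fully scripted, reproducible version of the workflow: material mapping from
CT grayscale, muscle-force loading, a static linear elastic solve, principal
and shear strain recovery, strain-gauge-site validation, and element-level
differential strain maps between model variants — exercised end-to-end on a
synthetic mandible phantom, so no scan data or commercial solver is needed.

## The model

**Geometry.** 4-node linear tetrahedra with named regions (`cortical`,
`trabecular`, `tooth`, `pdl`, `screw`) and node sets for constraints, muscle
insertions and gauge patches. Adjacent regions are tied by shared nodes on
conforming interfaces. Meshes are read/written in an Abaqus-INP subset
(`*NODE`, `*ELEMENT TYPE=C3D4`, `*NSET`, `*ELSET`), a native JSON format,
and legacy VTK for visualisation.

**Materials.** Cortical elasticity comes from an affine grayscale
calibration,

```
rho = -0.01979662 + 1.0577433 · GV
E   = -2.7501977952777819 + 0.0082389155811676013 · rho   (MPa, floored)
nu  =  0.400595880819907  - 0.00000913165104192569 · rho  (clamped)
```

quantised into 80 equal-width density bins (heterogeneous isotropic
assignment). Fixed properties: teeth E = 24 500 MPa, ν = 0.49; trabecular
10 000 MPa, 0.3; bone screws 105 000 MPa, 0.36. The PDL region is swapped
across variants: `PDL` (E = 0.68 MPa, the validated reference), `MODEL_1..4`
(0.07, 0.18, 13.8, 1750 MPa, all ν = 0.49) and `NO_PDL` (tooth properties,
i.e. the ligament "removed" by material swap on identical geometry).

**Loading.** Each of 10 jaw-elevator muscles (working/balancing deep and
superficial masseter, anterior and posterior temporalis, medial pterygoid)
pulls with |F| = PCSA × 30 N/cm² × normalized EMG from its insertion-node
centroid toward its cranial attachment, split equally over insertion nodes.
Chewing constraints: working-side occlusal bite surfaces fixed in all
directions (bite force emerges as reaction), working condyle node fixed,
balancing condyle node free only medio-laterally. An over-constrained
scenario (both condyles fully fixed) and a rescaled-activation scenario are
available.

**Solve and outputs.** Sparse direct static solve with constraints applied
by DOF elimination; per-element strain tensors (tensor-shear convention),
principal strains ε₁ (max) / ε₂ (min), anatomical shear components ε₁₂
(sagittal), ε₁₃ (frontal), ε₂₃ (transverse), all in microstrain; gauge-frame
rotations and in-plane principal orientations at rosette sites; boxplot
1.5×IQR whisker validation against in-vivo-style per-cycle samples; and
per-element differential maps between variant pairs.

Anatomical frame: X = superoinferior, Y = anteroposterior, Z = mediolateral
(the working side is +Z).

## Worked example

```python
from jawstrain.pipeline import RunConfig, run_experiment
from jawstrain.synth import PhantomSpec

manifest = run_experiment(RunConfig(
    outdir="results/study",
    phantom=PhantomSpec(seed=1),
    variants=("MODEL_1", "MODEL_2", "PDL", "MODEL_3", "MODEL_4", "NO_PDL"),
    pairs=(("PDL", "NO_PDL"), ("MODEL_1", "MODEL_4")),
    seed=1,
))
```

or, as a shell pipeline, the numbered drivers:

```
python analysis/01_make_inputs.py      # phantom mesh, grayscale, muscles, gauges, in-vivo samples
python analysis/02_verify_solver.py    # patch test + cantilever refinement
python analysis/03_run_variants.py     # the six-variant chewing study
python analysis/04_test_predictions.py # directional verdicts
python analysis/05_sensitivity_scenarios.py
```

`03` + `04` print (56 760-element phantom, seed 1):

```
alveolar-surface mean e1 (microstrain) by variant:
variant  alveolar_surface_mean_e1
MODEL_1                 66.430540
MODEL_2                 66.131785
    PDL                 64.921429
MODEL_3                 57.937126
MODEL_4                 50.035599
 NO_PDL                 37.415669

     P1 alveolar e1 non-increasing with PDL E 66.4 -> 66.1 -> 57.9 -> 50.0   True
P1 alveolar |e_min| non-increasing with PDL E 78.7 -> 78.2 -> 60.1 -> 45.0   True
          H2 tooth-root e1 higher without PDL                 34.9 vs 13.3   True
           H2 PDL-region e1 lower without PDL              28.6 vs 14143.7   True
        P3 alveolar |shear| lower without PDL                 11.9 vs 25.2   True
```

Reading: stiffening the PDL from 0.07 to 1750 MPa monotonically lowers
alveolar surface strain (a stiffer tooth–bone interface raises the jaw's
torsional rigidity), removing the PDL outright lowers surface and shear
strains further, and the ligament redirects load away from the tooth roots —
roots strain ~2.6× more once it is gone, while the (now stiff) ligament
region itself carries far less strain. The same sign pattern holds under the
over-constrained and full-activation scenarios (`results/scenarios.csv`).

A `jawstrain` CLI wraps the same library (`jawstrain synth phantom`,
`jawstrain run --config cfg.yaml`, `jawstrain validate ...`).

## Layout

```
src/jawstrain/   mesh.py       mesh container + INP/JSON/VTK I/O
                 materials.py  grayscale calibration + PDL variants
                 loads.py      muscle forces + constraint scenarios
                 fe.py         assembly, sparse solve, strain recovery
                 strain.py     principal/shear strains, gauges, diff maps
                 validation.py whisker/range/orientation verdicts
                 synth.py      phantom generator + synthetic inputs
                 pipeline.py   end-to-end orchestration
                 cli.py        click CLI
analysis/        numbered study drivers (write under results/)
scripts/         acceptance.py
tests/           pytest suite (unit, property and end-to-end)
docs/methods.md  modelling assumptions, conventions, limitations
```
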