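#!/usr/bin/env python
"""Solve the chewing load case for every PDL stiffness variant.

Runs the full pipeline on the phantom: the validated-model analogue (PDL,
E = 0.68 MPa), the four published alternatives (0.07, 0.18, 13.8, 1750 MPa)
and the material-swap NO_PDL model, then writes region summaries, gauge
readouts, element-level differential maps for the PDL-vs-NO_PDL and
MODEL_1-vs-MODEL_4 pairs, and gauge-validation verdicts against the
synthetic in-vivo samples from 01_make_inputs.py.

Writes results/study/.
"""

from pathlib import Path

import pandas as pd

from jawstrain.pipeline import RunConfig, run_experiment
from jawstrain.synth import PhantomSpec
from jawstrain.validation import read_invivo

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    invivo_path = ROOT / "inputs" / "invivo.csv"
    invivo = read_invivo(invivo_path) if invivo_path.exists() else None
    if invivo is None:
        print("note: run 01_make_inputs.py first for the validation stage")

    cfg = RunConfig(
        outdir=ROOT / "study",
        phantom=PhantomSpec(seed=SEED),
        variants=("MODEL_1", "MODEL_2", "PDL", "MODEL_3", "MODEL_4", "NO_PDL"),
        pairs=(("PDL", "NO_PDL"), ("MODEL_1", "MODEL_4")),
        invivo=invivo,
        seed=SEED,
    )
    manifest = run_experiment(cfg)
    print(f"solved {len(manifest['solves'])} variants on "
          f"{manifest['n_elements']} elements")
    for variant, info in manifest["solves"].items():
        print(f"  {variant:8s} residual {info['residual']:.1e} "
              f"equilibrium {info['equilibrium_residual']:.1e}")

    pred = pd.read_csv(ROOT / "study" / "predictions.csv")
    print("\nalveolar-surface mean e1 (microstrain) by variant:")
    print(pred[["variant", "alveolar_surface_mean_e1"]].to_string(index=False))


if __name__ == "__main__":
    main()
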