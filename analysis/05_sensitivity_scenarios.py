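#!/usr/bin/env python
"""Boundary-condition and activation sensitivity scenarios.

Re-runs the PDL vs NO_PDL comparison under (a) the over-constrained variant
(both condyles fixed in all directions) and (b) a uniform full-activation
muscle table (every EMG scale = 1), to check whether the directional
findings survive the two main modelling choices: condylar freedom and
activation scaling.

Writes results/scenarios.csv.
"""

from pathlib import Path

import pandas as pd

from jawstrain.loads import read_muscles
from jawstrain.pipeline import RunConfig, run_experiment
from jawstrain.synth import PhantomSpec, default_muscles

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    spec = PhantomSpec(seed=SEED)
    muscles_path = ROOT / "inputs" / "muscles.csv"
    muscles = (read_muscles(muscles_path) if muscles_path.exists()
               else default_muscles(spec))
    rows = []
    for label, scenario, override in [
        ("chewing", "chewing", None),
        ("overconstrained", "overconstrained", None),
        ("full_activation", "clenching-scaled", {m.name: 1.0 for m in muscles}),
    ]:
        out = ROOT / "scenarios" / label
        run_experiment(RunConfig(outdir=out, phantom=spec,
                                 variants=("PDL", "NO_PDL"), scenario=scenario,
                                 emg_override=override, seed=SEED,
                                 write_vtk_files=False))
        pred = pd.read_csv(out / "predictions.csv").set_index("variant")
        rows.append({
            "scenario": label,
            "alveolar_e1_pdl": pred.loc["PDL", "alveolar_surface_mean_e1"],
            "alveolar_e1_nopdl": pred.loc["NO_PDL", "alveolar_surface_mean_e1"],
            "root_e1_pdl": pred.loc["PDL", "tooth_root_mean_e1"],
            "root_e1_nopdl": pred.loc["NO_PDL", "tooth_root_mean_e1"],
            "shear_ratio_nopdl_over_pdl":
                pred.loc["NO_PDL", "alveolar_surface_mean_abs_shear"]
                / pred.loc["PDL", "alveolar_surface_mean_abs_shear"],
        })
        print(f"{label}: alveolar e1 PDL {rows[-1]['alveolar_e1_pdl']:.1f} vs "
              f"NO_PDL {rows[-1]['alveolar_e1_nopdl']:.1f} microstrain; "
              f"shear ratio {rows[-1]['shear_ratio_nopdl_over_pdl']:.2f}")

    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "scenarios.csv", index=False, float_format="%.6g")
    print(f"wrote {ROOT / 'scenarios.csv'}")


if __name__ == "__main__":
    main()
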