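#!/usr/bin/env python
"""Evaluate the study's directional predictions from the solved variants.

Reads results/study/predictions.csv (written by 03_run_variants.py) and
reports:

* Prediction 1 — alveolar-surface principal strains fall monotonically as
  PDL stiffness rises through 0.07, 0.18, 13.8, 1750 MPa;
* Hypothesis 2 — removing the PDL raises tooth-root strains and lowers
  PDL-region strains (the ligament redirects load into the alveolar bone);
* Prediction 3 — alveolar shear strains are lower without the PDL
  (a stiffer tooth-bone interface raises torsional rigidity).

Writes results/prediction_verdicts.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
E_ORDER = ["MODEL_1", "MODEL_2", "MODEL_3", "MODEL_4"]


def main() -> None:
    pred = pd.read_csv(ROOT / "study" / "predictions.csv").set_index("variant")
    rows = []

    series = pred.loc[E_ORDER, "alveolar_surface_mean_e1"].tolist()
    mono = all(b <= a * (1 + 1e-3) for a, b in zip(series, series[1:]))
    rows.append({"prediction": "P1 alveolar e1 non-increasing with PDL E",
                 "values": " -> ".join(f"{v:.1f}" for v in series), "holds": mono})

    series2 = pred.loc[E_ORDER, "alveolar_surface_mean_abs_emin"].tolist()
    mono2 = all(b <= a * (1 + 1e-3) for a, b in zip(series2, series2[1:]))
    rows.append({"prediction": "P1 alveolar |e_min| non-increasing with PDL E",
                 "values": " -> ".join(f"{v:.1f}" for v in series2), "holds": mono2})

    root_up = pred.loc["NO_PDL", "tooth_root_mean_e1"] > pred.loc["PDL", "tooth_root_mean_e1"]
    rows.append({"prediction": "H2 tooth-root e1 higher without PDL",
                 "values": f"{pred.loc['NO_PDL', 'tooth_root_mean_e1']:.1f} vs "
                           f"{pred.loc['PDL', 'tooth_root_mean_e1']:.1f}",
                 "holds": bool(root_up)})

    pdl_down = pred.loc["NO_PDL", "pdl_mean_e1"] < pred.loc["PDL", "pdl_mean_e1"]
    rows.append({"prediction": "H2 PDL-region e1 lower without PDL",
                 "values": f"{pred.loc['NO_PDL', 'pdl_mean_e1']:.1f} vs "
                           f"{pred.loc['PDL', 'pdl_mean_e1']:.1f}",
                 "holds": bool(pdl_down)})

    shear_down = (pred.loc["NO_PDL", "alveolar_surface_mean_abs_shear"]
                  < pred.loc["PDL", "alveolar_surface_mean_abs_shear"])
    rows.append({"prediction": "P3 alveolar |shear| lower without PDL",
                 "values": f"{pred.loc['NO_PDL', 'alveolar_surface_mean_abs_shear']:.1f} vs "
                           f"{pred.loc['PDL', 'alveolar_surface_mean_abs_shear']:.1f}",
                 "holds": bool(shear_down)})

    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "prediction_verdicts.csv", index=False)
    print(df.to_string(index=False))
    print(f"\n{int(df['holds'].sum())}/{len(df)} directional predictions hold"
          f" -> {ROOT / 'prediction_verdicts.csv'}")


if __name__ == "__main__":
    main()
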