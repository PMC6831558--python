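#!/usr/bin/env python
"""Generate every input of the study: the mandible phantom mesh, its cortical
grayscale field, the 10-muscle loading table, gauge definitions, and synthetic
in-vivo strain samples for the three gauge sites.

Writes results/inputs/ and prints a short inventory.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from jawstrain.loads import write_muscles
from jawstrain.mesh import write_json
from jawstrain.synth import (PhantomSpec, default_gauges, default_muscles,
                             make_grayscale, make_invivo, make_phantom)
from jawstrain.validation import write_invivo

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 1

# planted in-vivo spreads per gauge (microstrain medians/IQRs and an
# orientation arc), emulating per-cycle rosette records during nut chewing
INVIVO_PLANTS = {
    "ULAT": (dict(median=150.0, iqr=80.0, min=15.0, max=271.0),
             dict(median=-141.0, iqr=75.0, min=-249.0, max=-12.0), (20.0, 130.0)),
    "LLAT": (dict(median=103.0, iqr=60.0, min=10.0, max=208.0),
             dict(median=-84.0, iqr=50.0, min=-168.0, max=-4.0), (230.0, 120.0)),
    "MED": (dict(median=59.0, iqr=40.0, min=15.0, max=203.0),
            dict(median=-72.0, iqr=45.0, min=-208.0, max=-28.0), (260.0, 110.0)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = PhantomSpec(seed=SEED)
    mesh = make_phantom(spec)
    write_json(mesh, OUT / "phantom.json")
    counts = dict(zip(*np.unique(mesh.region, return_counts=True)))
    print(f"phantom: {mesh.n_nodes} nodes, {mesh.n_elements} tets "
          f"({ {k: int(v) for k, v in counts.items()} })")

    gv = make_grayscale(mesh, seed=SEED)
    pd.DataFrame({"element_id": np.arange(mesh.n_elements), "gv": gv}).to_csv(
        OUT / "grayscale.csv", index=False, float_format="%.10g")
    ok = np.isfinite(gv)
    print(f"grayscale: {ok.sum()} cortical values in [{gv[ok].min():.4g}, {gv[ok].max():.4g}]")

    muscles = default_muscles(spec)
    write_muscles(muscles, OUT / "muscles.csv")
    print(f"muscles: {len(muscles)} (synthetic PCSA/EMG stand-ins, 5 per side)")

    gauges = default_gauges(spec)
    (OUT / "gauges.json").write_text(json.dumps(
        [{"name": g.name, "center": g.center.tolist(), "radius": g.radius,
          "rotation": g.rotation.tolist()} for g in gauges], indent=2))
    print(f"gauges: {[g.name for g in gauges]}")

    samples = {
        name: make_invivo(name, 148, e1_plant=e1, emin_plant=emin,
                          orientation_arc=arc, seed=SEED + i)
        for i, (name, (e1, emin, arc)) in enumerate(INVIVO_PLANTS.items())
    }
    write_invivo(samples, OUT / "invivo.csv")
    print(f"in-vivo: 148 synthetic cycles per gauge -> {OUT / 'invivo.csv'}")


if __name__ == "__main__":
    main()
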