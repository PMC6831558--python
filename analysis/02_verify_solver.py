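#!/usr/bin/env python
"""Solver verification against closed-form elasticity solutions.

Two classical checks: the uniaxial patch test (constant-strain tets must
reproduce a uniform strain state exactly) and a slender cantilever (L/h = 10)
whose tip deflection must converge to the Euler-Bernoulli value PL^3/3EI.

Writes results/solver_verification.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))
from acceptance import box_mesh, patch_test  # noqa: E402

from jawstrain.fe import solve_static  # noqa: E402
from jawstrain.loads import ConstraintSpec, LoadCase  # noqa: E402
from jawstrain.materials import MaterialField  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    err, n = patch_test()
    rows.append({"check": "patch_test", "n_elements": n, "value": err,
                 "target": "max |eps_xx - sigma/E| / (sigma/E)"})
    print(f"patch test: max relative strain deviation {err:.2e} over {n} tets")

    E, v, P, L, W, H = 1000.0, 0.3, 1.0, 20.0, 1.0, 2.0
    ref = P * L**3 / (3.0 * E * (W * H**3 / 12.0))
    for nx, nz in [(40, 8), (60, 12), (80, 16)]:
        mesh = box_mesh(nx, 1, nz, L, W, H)
        tip = mesh.node_sets["face_xL"]
        case = LoadCase(
            nodal_forces={int(i): np.array([0.0, 0.0, P / tip.size]) for i in tip},
            constraints=[ConstraintSpec("face_x0", ("X", "Y", "Z"))])
        mat = MaterialField(E=np.full(mesh.n_elements, E), v=np.full(mesh.n_elements, v))
        disp, info = solve_static(mesh, mat, case)
        w_tip = float(disp.u[tip, 2].mean())
        rows.append({"check": f"cantilever_{nx}x1x{nz}", "n_elements": mesh.n_elements,
                     "value": 100.0 * (w_tip - ref) / ref,
                     "target": "tip deflection error vs PL^3/3EI, %"})
        print(f"cantilever {nx}x1x{nz}: tip {w_tip:.5f} mm vs {ref:.5f} mm "
              f"({100.0 * (w_tip - ref) / ref:+.2f}%), equilibrium residual "
              f"{info.equilibrium_residual:.1e}")

    pd.DataFrame(rows).to_csv(OUT / "solver_verification.csv", index=False,
                              float_format="%.6g")
    print(f"wrote {OUT / 'solver_verification.csv'}")


if __name__ == "__main__":
    main()
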