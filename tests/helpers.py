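"""Shared test utilities: structured box meshes and independent oracles."""

from __future__ import annotations

import numpy as np

from jawstrain.mesh import TetMesh

# the 6 edge-paths from corner (0,0,0) to (1,1,1) of a hex cell
KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def box_mesh(nx: int, ny: int, nz: int, L: float, W: float, H: float) -> TetMesh:
    """Structured box [0,L]x[0,W]x[0,H] split into 6 tets per cell, with
    node sets ``face_x0`` / ``face_xL`` on the two x-extreme faces."""

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    nodes = np.array(
        [[i * L / nx, j * W / ny, k * H / nz]
         for i in range(nx + 1) for j in range(ny + 1) for k in range(nz + 1)]
    )
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = {}
                for d in range(8):
                    di, dj, dk = d & 1, (d >> 1) & 1, (d >> 2) & 1
                    c[(di, dj, dk)] = nid(i + di, j + dj, k + dk)
                for perm in KUHN_PERMS:
                    path = [(0, 0, 0)]
                    cur = [0, 0, 0]
                    for ax in perm:
                        cur[ax] = 1
                        path.append(tuple(cur))
                    tets.append([c[q] for q in path])
    mesh = TetMesh(nodes=nodes, tets=np.array(tets),
                   region=np.full(len(tets), "cortical"))
    mesh.repair_orientation()
    mesh.node_sets = {
        "face_x0": np.flatnonzero(mesh.nodes[:, 0] < 1e-12),
        "face_xL": np.flatnonzero(np.abs(mesh.nodes[:, 0] - L) < 1e-9),
    }
    mesh.validate()
    return mesh


def affine_fit_strain(coords: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Independent per-element strain: least-squares affine fit u = a + G x,
    symmetrised.  Returns a 3x3 tensor."""
    A = np.hstack([np.ones((4, 1)), coords])  # (4, 4)
    coef, *_ = np.linalg.lstsq(A, u, rcond=None)  # (4, 3): rows = [a; G^T]
    G = coef[1:].T
    return 0.5 * (G + G.T)


def element_energy(coords: np.ndarray, u: np.ndarray, E: float, v: float) -> float:
    """Strain energy of one constant-strain tet from the affine-fit strain."""
    eps = affine_fit_strain(coords, u.reshape(4, 3))
    lam = E * v / ((1 + v) * (1 - 2 * v))
    mu = E / (2 * (1 + v))
    vol = abs(np.linalg.det(np.hstack([np.ones((4, 1)), coords]))) / 6.0
    tr = np.trace(eps)
    return vol * (0.5 * lam * tr**2 + mu * np.sum(eps * eps))


def hessian_stiffness(coords: np.ndarray, E: float, v: float, h: float = 1e-4) -> np.ndarray:
    """Energy-Hessian oracle for the element stiffness.

    The energy is exactly quadratic in the nodal displacements, so central
    second differences are exact up to roundoff.
    """
    K = np.zeros((12, 12))
    for i in range(12):
        for j in range(i, 12):
            def U(si, sj):
                u = np.zeros(12)
                u[i] += si * h
                u[j] += sj * h
                return element_energy(coords, u, E, v)

            K[i, j] = (U(1, 1) - U(1, -1) - U(-1, 1) + U(-1, -1)) / (4 * h * h)
            K[j, i] = K[i, j]
    return K
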