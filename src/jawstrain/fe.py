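"""Static linear elastic finite-element solver on 4-node tetrahedra.

Small-strain, isotropic-heterogeneous, constant-strain tets.  The global
stiffness is assembled sparse, zero-displacement constraints are applied by
row/column elimination (exact satisfaction, clean reaction recovery) and the
reduced system is solved with a direct sparse LU factorisation — mirroring
an implicit direct static solve.  Strain tensors are stored with the tensor
shear convention eps_ij = (du_i/dx_j + du_j/dx_i) / 2; engineering shear
(gamma = 2 eps) is available through an explicit accessor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .loads import LoadCase
from .materials import MaterialField
from .mesh import TetMesh

#: Voigt component order used throughout (engineering shear in assembly)
VOIGT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")


class SolveError(RuntimeError):
    """Raised when the constrained system cannot be solved."""


def isotropic_D(E: float, v: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in engineering-Voigt form (MPa)."""
    lam = E * v / ((1.0 + v) * (1.0 - 2.0 * v))
    mu = E / (2.0 * (1.0 + v))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def shape_gradients(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the 4 linear shape functions and signed volumes.

    Parameters
    ----------
    nodes : (m, 4, 3) element node coordinates.

    Returns
    -------
    grads : (m, 4, 3) with grads[e, i] = grad N_i on element e
    vol : (m,) signed volumes (mm^3)
    """
    nodes = np.asarray(nodes, dtype=float)
    squeeze = nodes.ndim == 2
    if squeeze:
        nodes = nodes[None]
    m = nodes.shape[0]
    C = np.concatenate([np.ones((m, 4, 1)), nodes], axis=2)  # (m,4,4)
    det = np.linalg.det(C)
    vol = det / 6.0
    grads = np.linalg.inv(C)[:, 1:, :].transpose(0, 2, 1)  # (m,4,3)
    if squeeze:
        return grads[0], vol[0]
    return grads, vol


def b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, engineering-Voigt: (m, 6, 12)."""
    grads = np.asarray(grads)
    squeeze = grads.ndim == 2
    if squeeze:
        grads = grads[None]
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for i in range(4):
        gx, gy, gz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 0] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 1] = gz
        B[:, 5, c + 2] = gy
    return B[0] if squeeze else B


def element_stiffness(nodes: np.ndarray, E: float, v: float) -> np.ndarray:
    """12x12 stiffness (N/mm) of one constant-strain tet; errors on degeneracy."""
    nodes = np.asarray(nodes, dtype=float)
    vol = np.linalg.det(np.concatenate([np.ones((4, 1)), nodes], axis=1)) / 6.0
    if vol <= 0.0:
        raise ValueError(f"degenerate tet (signed volume {vol:.3g} mm^3)")
    grads, vol = shape_gradients(nodes)
    B = b_matrix(grads)
    return vol * B.T @ isotropic_D(E, v) @ B


@dataclass
class Displacements:
    """Per-node displacement triples, mm."""

    u: np.ndarray  # (n, 3)


@dataclass
class StrainField:
    """Per-element small-strain tensors, tensor-shear convention.

    ``tensor`` columns follow :data:`VOIGT_ORDER`; values are dimensionless
    strain (multiply by 1e6 for microstrain).
    """

    tensor: np.ndarray  # (m, 6) with eps_xy, eps_xz, eps_yz tensor shears

    @property
    def microstrain(self) -> np.ndarray:
        return self.tensor * 1e6

    def engineering(self) -> np.ndarray:
        """Copy with engineering shears gamma = 2 eps in the last 3 columns."""
        out = self.tensor.copy()
        out[:, 3:] *= 2.0
        return out

    def as_matrices(self) -> np.ndarray:
        """(m, 3, 3) symmetric tensor matrices."""
        t = self.tensor
        M = np.empty((t.shape[0], 3, 3))
        M[:, 0, 0], M[:, 1, 1], M[:, 2, 2] = t[:, 0], t[:, 1], t[:, 2]
        M[:, 0, 1] = M[:, 1, 0] = t[:, 3]
        M[:, 0, 2] = M[:, 2, 0] = t[:, 4]
        M[:, 1, 2] = M[:, 2, 1] = t[:, 5]
        return M


@dataclass
class SolveInfo:
    """Diagnostics of one static solve."""

    residual: float  # ||K u - f|| / ||f|| on free DOFs
    reaction_sum: np.ndarray  # (3,) sum of constraint reactions, N
    applied_sum: np.ndarray  # (3,) sum of applied nodal forces, N
    equilibrium_residual: float  # |reactions + applied| / |applied|
    n_free_dofs: int


def assemble_stiffness(mesh: TetMesh, materials: MaterialField) -> sp.csr_matrix:
    """Assemble the global sparse stiffness (N/mm), 3 DOFs per node."""
    grads, vol = shape_gradients(mesh.nodes[mesh.tets])
    if np.any(vol <= 0.0):
        raise ValueError("mesh contains non-positive-volume tets; repair orientation first")
    B = b_matrix(grads)  # (m,6,12)

    E, v = materials.E, materials.v
    lam = E * v / ((1.0 + v) * (1.0 - 2.0 * v))
    mu = E / (2.0 * (1.0 + v))
    D = np.zeros((mesh.n_elements, 6, 6))
    D[:, :3, :3] = lam[:, None, None]
    D[:, [0, 1, 2], [0, 1, 2]] += 2.0 * mu[:, None]
    D[:, [3, 4, 5], [3, 4, 5]] = mu[:, None]

    Ke = vol[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, D, B, optimize=True)

    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(3 * mesh.n_nodes,) * 2)
    return K.tocsr()


def solve_static(
    mesh: TetMesh,
    materials: MaterialField,
    load: LoadCase,
    residual_tol: float = 1e-8,
) -> tuple[Displacements, SolveInfo]:
    """Solve K u = f with zero-displacement constraints by DOF elimination."""
    K = assemble_stiffness(mesh, materials)
    f = load.force_vector(mesh.n_nodes).ravel()
    fixed = load.fixed_dof_mask(mesh).ravel()
    free = ~fixed
    if free.all():
        raise SolveError("no constraints given: rigid-body modes make the system singular")

    Kff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(Kff)
        uf = lu.solve(f[free])
    except RuntimeError as exc:
        raise SolveError(
            "constrained stiffness is singular — check that the constraint "
            f"sets remove all rigid-body modes ({exc})"
        ) from exc
    if not np.all(np.isfinite(uf)):
        raise SolveError("solver returned non-finite displacements; system likely singular")

    fn = np.linalg.norm(f[free])
    residual = float(np.linalg.norm(Kff @ uf - f[free]) / (fn if fn > 0 else 1.0))
    if residual > residual_tol:
        raise SolveError(f"relative residual {residual:.3e} exceeds tolerance {residual_tol:.1e}")

    u = np.zeros(3 * mesh.n_nodes)
    u[free] = uf
    # reactions at constrained DOFs; global equilibrium follows from K's
    # translational nullspace and is reported as a diagnostic
    rfix = np.where(fixed.reshape(-1, 3), (K @ u - f).reshape(-1, 3), 0.0)
    reaction_sum = rfix.sum(axis=0)
    applied_sum = load.force_vector(mesh.n_nodes).sum(axis=0)
    denom = np.linalg.norm(applied_sum) if np.linalg.norm(applied_sum) > 0 else 1.0
    eq = float(np.linalg.norm(reaction_sum + applied_sum) / denom)
    info = SolveInfo(
        residual=residual,
        reaction_sum=reaction_sum,
        applied_sum=applied_sum,
        equilibrium_residual=eq,
        n_free_dofs=int(free.sum()),
    )
    return Displacements(u=u.reshape(-1, 3)), info


def recover_strains(mesh: TetMesh, disp: Displacements) -> StrainField:
    """Constant per-element strain from the linear shape-function gradients."""
    grads, _ = shape_gradients(mesh.nodes[mesh.tets])
    B = b_matrix(grads)  # engineering Voigt
    ue = disp.u[mesh.tets].reshape(mesh.n_elements, 12)
    eng = np.einsum("eij,ej->ei", B, ue)
    eng[:, 3:] /= 2.0  # to tensor shear
    return StrainField(tensor=eng)
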