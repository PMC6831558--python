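import numpy as np
import pytest

from jawstrain.fe import (SolveError, assemble_stiffness, element_stiffness,
                          recover_strains, solve_static, Displacements)
from jawstrain.loads import ConstraintSpec, LoadCase
from jawstrain.materials import MaterialField

from helpers import affine_fit_strain, box_mesh, hessian_stiffness

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


def random_tet(rng):
    while True:
        t = rng.normal(size=(4, 3))
        vol = np.linalg.det(np.hstack([np.ones((4, 1)), t])) / 6.0
        if vol > 0.05:
            return t


def uniform_material(mesh, E=1000.0, v=0.3):
    return MaterialField(E=np.full(mesh.n_elements, E), v=np.full(mesh.n_elements, v))


# ---------------------------------------------------------------------------
# element stiffness
# ---------------------------------------------------------------------------

def test_stiffness_symmetric_with_rigid_nullspace(rng):
    for _ in range(5):
        K = element_stiffness(random_tet(rng), E=7.0, v=0.34)
        assert np.abs(K - K.T).max() <= 1e-12 * np.abs(K).max()
        for ax in range(3):
            t = np.zeros(12)
            t[ax::3] = 1.0  # rigid translation
            assert np.abs(K @ t).max() <= 1e-9 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert np.all(w[6:] > 1e-8 * w[-1])  # 6-dimensional nullspace
        assert np.abs(w[:6]).max() <= 1e-9 * w[-1]


def test_stiffness_matches_energy_hessian(rng):
    """Central-difference Hessian of the affine-fit strain energy (exact for
    a quadratic energy) reproduces the assembled element stiffness."""
    cases = [ (UNIT_TET, 1.0, 0.3) ] + [(random_tet(rng), 250.0, 0.45) for _ in range(3)]
    for coords, E, v in cases:
        K = element_stiffness(coords, E, v)
        K_oracle = hessian_stiffness(coords, E, v)
        assert np.abs(K - K_oracle).max() <= 1e-8 * np.abs(K_oracle).max()


def test_degenerate_tet_rejected():
    flat = UNIT_TET.copy()
    flat[3] = [0.5, 0.5, 0.0]
    with pytest.raises(ValueError, match="degenerate"):
        element_stiffness(flat, 1.0, 0.3)


# ---------------------------------------------------------------------------
# global solve
# ---------------------------------------------------------------------------

def cantilever(nx=80, ny=1, nz=16, L=20.0, W=1.0, H=2.0, E=1000.0, v=0.3, P=1.0):
    mesh = box_mesh(nx, ny, nz, L, W, H)
    tip = mesh.node_sets["face_xL"]
    forces = {int(n): np.array([0.0, 0.0, P / tip.size]) for n in tip}
    case = LoadCase(nodal_forces=forces,
                    constraints=[ConstraintSpec("face_x0", ("X", "Y", "Z"))])
    return mesh, uniform_material(mesh, E, v), case


def test_zero_load_zero_displacement():
    mesh, mat, _ = cantilever(nx=10, nz=4)
    case = LoadCase(nodal_forces={},
                    constraints=[ConstraintSpec("face_x0", ("X", "Y", "Z"))])
    disp, info = solve_static(mesh, mat, case)
    assert np.abs(disp.u).max() == 0.0


def test_uniaxial_patch_test():
    """Linear tets reproduce a constant stress state exactly: consistent end
    tractions on a box give uniform strain eps_xx = sigma/E everywhere."""
    E, v, sigma = 1000.0, 0.3, 2.0
    L, W, H = 4.0, 2.0, 2.0
    mesh = box_mesh(4, 2, 2, L, W, H)
    # consistent nodal loads on the x = L face: each boundary triangle
    # contributes area/3 to its three nodes
    from jawstrain.mesh import extract_surface
    surf = extract_surface(mesh)
    fc = surf.face_centroids(mesh)
    forces: dict[int, np.ndarray] = {}
    for f, c in zip(surf.faces, fc):
        if abs(c[0] - L) > 1e-9:
            continue
        p = mesh.nodes[f]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        for n in f:
            forces.setdefault(int(n), np.zeros(3))
            forces[int(n)] += np.array([sigma * area / 3.0, 0.0, 0.0])
    # minimal constraints: x=0 plane in X, plus two pins to kill rigid modes
    mesh.node_sets["pin_origin"] = np.array([np.argmin(np.linalg.norm(mesh.nodes, axis=1))])
    far = np.argmin(np.linalg.norm(mesh.nodes - [0.0, 0.0, H], axis=1))
    mesh.node_sets["pin_z"] = np.array([far])
    case = LoadCase(
        nodal_forces=forces,
        constraints=[ConstraintSpec("face_x0", ("X",)),
                     ConstraintSpec("pin_origin", ("Y", "Z")),
                     ConstraintSpec("pin_z", ("Y",))])
    disp, info = solve_static(mesh, uniform_material(mesh, E, v), case)
    strains = recover_strains(mesh, disp)
    exx = strains.tensor[:, 0]
    target = sigma / E
    assert np.abs(exx - target).max() <= 1e-10 * abs(target)
    np.testing.assert_allclose(strains.tensor[:, 1], -v * target, rtol=0, atol=1e-10 * target)
    assert info.equilibrium_residual <= 1e-8


def test_cantilever_tip_deflection_within_5pct():
    mesh, mat, case = cantilever()
    disp, info = solve_static(mesh, mat, case)
    tip = mesh.node_sets["face_xL"]
    w_tip = disp.u[tip, 2].mean()
    I = 1.0 * 2.0**3 / 12.0
    ref = 1.0 * 20.0**3 / (3.0 * 1000.0 * I)
    assert abs(w_tip - ref) / ref < 0.05
    assert info.residual <= 1e-8 and info.equilibrium_residual <= 1e-8


def test_cantilever_refinement_converges_monotonically():
    errors = []
    I = 1.0 * 2.0**3 / 12.0
    ref = 1.0 * 20.0**3 / (3.0 * 1000.0 * I)
    for nx, nz in [(40, 8), (60, 12), (80, 16)]:
        mesh, mat, case = cantilever(nx=nx, nz=nz)
        disp, _ = solve_static(mesh, mat, case)
        w_tip = disp.u[mesh.node_sets["face_xL"], 2].mean()
        errors.append(abs(w_tip - ref) / ref)
    assert errors[0] > errors[1] > errors[2]


def test_insufficient_constraints_raise():
    mesh = box_mesh(2, 2, 2, 1, 1, 1)
    mat = uniform_material(mesh)
    with pytest.raises(SolveError, match="no constraints"):
        solve_static(mesh, mat, LoadCase(nodal_forces={}, constraints=[]))
    mesh.node_sets["one"] = np.array([0])
    case = LoadCase(nodal_forces={int(mesh.n_nodes - 1): np.array([0.0, 1.0, 0.0])},
                    constraints=[ConstraintSpec("one", ("X",))])
    with pytest.raises(SolveError):
        solve_static(mesh, mat, case)


def test_free_free_stiffness_has_six_zero_modes():
    mesh = box_mesh(2, 1, 1, 2, 1, 1)  # 36 DOFs
    K = assemble_stiffness(mesh, uniform_material(mesh)).toarray()
    w = np.abs(np.linalg.eigvalsh(K))
    w.sort()
    assert w[5] <= 1e-9 * w[-1]
    assert w[6] > 1e-6 * w[-1]


def test_strain_energy_nonnegative(rng):
    mesh = box_mesh(2, 2, 2, 1, 1, 1)
    K = assemble_stiffness(mesh, uniform_material(mesh))
    for _ in range(5):
        u = rng.normal(size=3 * mesh.n_nodes)
        assert u @ (K @ u) >= -1e-9 * np.abs(u @ (K @ u))


def test_solution_invariant_under_node_permutation(rng):
    mesh, mat, case = cantilever(nx=10, ny=1, nz=4)
    disp, _ = solve_static(mesh, mat, case)
    perm = rng.permutation(mesh.n_nodes)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(mesh.n_nodes)
    from jawstrain.mesh import TetMesh
    permuted = TetMesh(nodes=mesh.nodes[perm], tets=inv[mesh.tets],
                       region=mesh.region.copy(),
                       node_sets={k: inv[v] for k, v in mesh.node_sets.items()})
    permuted.repair_orientation()
    case2 = LoadCase(nodal_forces={int(inv[n]): f for n, f in case.nodal_forces.items()},
                     constraints=case.constraints)
    disp2, _ = solve_static(permuted, mat, case2)
    scale = np.abs(disp.u).max()
    assert np.abs(disp2.u[inv] - disp.u).max() <= 1e-9 * scale


# ---------------------------------------------------------------------------
# strain recovery
# ---------------------------------------------------------------------------

def test_affine_displacement_recovers_exact_strain(rng):
    mesh = box_mesh(3, 3, 3, 2, 2, 2)
    A = np.array([[3.0, 1.0, -2.0], [1.0, -1.5, 0.5], [-2.0, 0.5, 2.2]]) * 1e-4
    disp = Displacements(u=mesh.nodes @ A.T)
    strains = recover_strains(mesh, disp)
    expected = np.array([A[0, 0], A[1, 1], A[2, 2], A[0, 1], A[0, 2], A[1, 2]])
    assert np.abs(strains.tensor - expected).max() <= 1e-12


def test_rigid_motion_gives_negligible_strain():
    mesh = box_mesh(3, 3, 3, 2, 2, 2)
    translation = Displacements(u=np.tile([0.3, -0.1, 0.7], (mesh.n_nodes, 1)))
    assert np.abs(recover_strains(mesh, translation).tensor).max() <= 1e-15
    # small rigid rotation: strain vanishes to linearisation order
    theta = 1e-6
    W = np.array([[0, -theta, 0], [theta, 0, 0], [0, 0, 0]])
    rot = Displacements(u=mesh.nodes @ W.T)
    assert np.abs(recover_strains(mesh, rot).tensor).max() <= 1e-9


def test_strain_matches_central_difference_oracle(rng):
    """Random nodal field: FE strain equals central differences of the FE
    interpolant around each centroid (the interpolant is affine per element)."""
    mesh = box_mesh(3, 2, 2, 3, 2, 2)
    u = rng.normal(scale=1e-3, size=(mesh.n_nodes, 3))
    strains = recover_strains(mesh, Displacements(u=u))
    h = 1e-4
    for e in rng.choice(mesh.n_elements, size=20, replace=False):
        coords = mesh.nodes[mesh.tets[e]]
        ue = u[mesh.tets[e]]
        A = np.hstack([np.ones((4, 1)), coords])

        def interp(x):
            bary = np.linalg.solve(A.T, np.array([1.0, *x]))
            return bary @ ue

        c = coords.mean(axis=0)
        G = np.empty((3, 3))
        for ax in range(3):
            step = np.zeros(3)
            step[ax] = h
            G[:, ax] = (interp(c + step) - interp(c - step)) / (2 * h)
        eps = 0.5 * (G + G.T)
        expected = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                             eps[0, 1], eps[0, 2], eps[1, 2]])
        np.testing.assert_allclose(strains.tensor[e], expected,
                                   rtol=1e-6, atol=1e-6 * np.abs(expected).max())


def test_affine_fit_oracle_agrees(rng):
    # cross-check the affine-fit oracle itself against the B-matrix path
    mesh = box_mesh(2, 2, 2, 1, 1, 1)
    u = rng.normal(scale=1e-3, size=(mesh.n_nodes, 3))
    strains = recover_strains(mesh, Displacements(u=u))
    for e in range(0, mesh.n_elements, 7):
        eps = affine_fit_strain(mesh.nodes[mesh.tets[e]], u[mesh.tets[e]])
        expected = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                             eps[0, 1], eps[0, 2], eps[1, 2]])
        np.testing.assert_allclose(strains.tensor[e], expected, rtol=1e-9,
                                   atol=1e-15)
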