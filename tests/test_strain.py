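import numpy as np
import pytest

from jawstrain.fe import StrainField
from jawstrain.mesh import extract_surface
from jawstrain.strain import (GaugeSite, differential_map, gauge_readout,
                              inplane_principal, principal, region_summary,
                              rotate_tensor, shear_components)
from jawstrain.synth import default_gauges


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q.T


def random_tensor(rng, n=1):
    return rng.normal(scale=100.0, size=(n, 6))


def test_principal_diagonal_tensor():
    pr = principal(np.array([100.0, -50.0, 0.0, 0.0, 0.0, 0.0]))
    assert pr.e1 == pytest.approx(100.0)
    assert pr.e_min == pytest.approx(-50.0)
    np.testing.assert_allclose(pr.values, [100.0, 0.0, -50.0])


def test_pure_shear_mohr_circle():
    # eps_xy = 100: principal +/-100 at 45 degrees in plane
    pr = principal(np.array([0.0, 0.0, 0.0, 100.0, 0.0, 0.0]))
    assert pr.e1 == pytest.approx(100.0)
    assert pr.e_min == pytest.approx(-100.0)
    e1, e2, theta = inplane_principal(np.array(0.0), np.array(0.0), np.array(100.0))
    assert e1 == pytest.approx(100.0) and e2 == pytest.approx(-100.0)
    assert theta == pytest.approx(45.0)


def test_principal_matches_characteristic_polynomial(rng):
    """Eigenvalues against the cubic-root oracle from tensor invariants."""
    for t in random_tensor(rng, 25):
        M = np.array([[t[0], t[3], t[4]], [t[3], t[1], t[5]], [t[4], t[5], t[2]]])
        i1 = np.trace(M)
        i2 = 0.5 * (i1**2 - np.trace(M @ M))
        i3 = np.linalg.det(M)
        roots = np.sort(np.roots([1.0, -i1, i2, -i3]).real)[::-1]
        pr = principal(t)
        np.testing.assert_allclose(pr.values, roots, rtol=1e-9, atol=1e-9 * np.abs(roots).max())
        # trace and orthonormality invariants
        assert pr.values.sum() == pytest.approx(i1, rel=1e-9)
        np.testing.assert_allclose(pr.axes @ pr.axes.T, np.eye(3), atol=1e-10)


def test_rotate_identity_and_quarter_turn():
    t = np.array([10.0, -4.0, 2.0, 3.0, -1.0, 0.5])
    np.testing.assert_allclose(rotate_tensor(t, np.eye(3)), t)
    # 90 degree rotation about z: x' = y, y' = -x
    R = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    out = rotate_tensor(t, R)
    assert out[0] == pytest.approx(t[1])  # exx' = eyy
    assert out[1] == pytest.approx(t[0])
    assert out[3] == pytest.approx(-t[3])  # exy' = -exy


def test_rotation_preserves_principal_values(rng):
    for t in random_tensor(rng, 10):
        R = random_rotation(rng)
        a = principal(t).values
        b = principal(rotate_tensor(t, R)).values
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-9 * np.abs(a).max())


def test_non_orthonormal_rotation_rejected():
    with pytest.raises(ValueError, match="orthonormal"):
        rotate_tensor(np.zeros(6), np.eye(3) * 2.0)


def test_shear_components_conventions(rng):
    t = np.array([0.0, 0.0, 0.0, 50.0, 0.0, 0.0])
    np.testing.assert_allclose(shear_components(t), [50.0, 0.0, 0.0])
    dil = np.array([7.0, 7.0, 7.0, 0.0, 0.0, 0.0])
    R = random_rotation(rng)
    np.testing.assert_allclose(shear_components(dil, R), 0.0, atol=1e-12)
    for t in random_tensor(rng, 5):
        R = random_rotation(rng)
        M = np.array([[t[0], t[3], t[4]], [t[3], t[1], t[5]], [t[4], t[5], t[2]]])
        Mr = R @ M @ R.T
        np.testing.assert_allclose(shear_components(t, R),
                                   [Mr[0, 1], Mr[0, 2], Mr[1, 2]], rtol=1e-9,
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# gauges
# ---------------------------------------------------------------------------

def test_gauge_uniform_field_single_orientation(small_mesh):
    """A uniform uniaxial field reads identically across the patch with the
    e1 axis along the gauge local x."""
    m = small_mesh.n_elements
    tensor = np.tile([100e-6, -30e-6, -30e-6, 0.0, 0.0, 0.0], (m, 1))
    surf = extract_surface(small_mesh)
    center = surf.face_centroids(small_mesh)[0]
    site = GaugeSite(name="G", center=center, radius=3.0, rotation=np.eye(3))
    ro = gauge_readout(small_mesh, StrainField(tensor=tensor), site, surface=surf)
    np.testing.assert_allclose(ro.e1, 100e-6, rtol=1e-12)
    np.testing.assert_allclose(ro.orientation_deg, 0.0, atol=1e-9)


def test_gauge_patch_matches_bruteforce_filter(small_mesh, small_solution, small_spec):
    strains = small_solution["strains"]
    surf = extract_surface(small_mesh)
    for site in default_gauges(small_spec):
        ro = gauge_readout(small_mesh, strains, site, surface=surf)
        # exhaustive scan over boundary faces
        expected = set()
        for f, owner in zip(surf.faces, surf.owners):
            c = small_mesh.nodes[f].mean(axis=0)
            if np.sqrt(((c - site.center) ** 2).sum()) <= site.radius:
                expected.add(int(owner))
        assert set(ro.element_ids.tolist()) == expected
        assert np.all((ro.orientation_deg >= 0) & (ro.orientation_deg < 360))


def test_gauge_infinite_radius_covers_surface(small_mesh, small_solution):
    surf = extract_surface(small_mesh)
    site = GaugeSite(name="ALL", center=[0.0, 0.0, 0.0], radius=1e9, rotation=np.eye(3))
    ro = gauge_readout(small_mesh, small_solution["strains"], site, surface=surf)
    assert set(ro.element_ids.tolist()) == set(np.unique(surf.owners).tolist())


def test_gauge_empty_patch_suggests_radius(small_mesh, small_solution):
    site = GaugeSite(name="FAR", center=[500.0, 500.0, 500.0], radius=0.1,
                     rotation=np.eye(3))
    with pytest.raises(ValueError, match="radius"):
        gauge_readout(small_mesh, small_solution["strains"], site)


# ---------------------------------------------------------------------------
# differential maps and summaries
# ---------------------------------------------------------------------------

def test_differential_map_properties(rng):
    a = rng.normal(size=500)
    b = rng.normal(size=500)
    same = differential_map(a, a, "e1")
    assert np.all(same.delta == 0.0)
    d = differential_map(a, b, "e1", pair=("PDL", "NO_PDL"))
    np.testing.assert_array_equal(d.swapped().delta, -d.delta)
    # element-wise loop oracle
    expected = np.array([a[i] - b[i] for i in range(a.size)])
    np.testing.assert_array_equal(d.delta, expected)
    with pytest.raises(ValueError, match="same mesh"):
        differential_map(a, b[:10], "e1")


def test_region_summary_examples():
    s = region_summary(np.full(10, 100.0), np.arange(10), name="c")
    assert (s.mean, s.sd, s.min, s.max) == (100.0, 0.0, 100.0, 100.0)
    s = region_summary(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 2]))
    assert s.mean == 2.0 and s.min == 1.0 and s.max == 3.0 and s.n == 3
    single = region_summary(np.array([5.0]), np.array([0]))
    assert single.sd == 0.0
    with pytest.raises(ValueError, match="empty"):
        region_summary(np.array([1.0]), np.array([], dtype=int))


def test_region_summary_matches_two_pass_oracle(rng):
    values = rng.normal(size=400)
    ids = rng.choice(400, size=97, replace=False)
    s = region_summary(values, ids)
    v = values[ids]
    mean = sum(v) / len(v)
    sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
    assert s.mean == pytest.approx(mean, rel=1e-12)
    assert s.sd == pytest.approx(sd, rel=1e-12)
    assert s.min <= s.mean <= s.max
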