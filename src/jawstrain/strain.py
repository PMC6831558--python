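"""Principal strains, gauge-frame rotation, differential maps, region summaries.

Conventions
-----------
* Reported "e1" is the maximum principal strain and reported "e2" the
  minimum principal strain: for volume elements that is the smallest
  eigenvalue of the 3D tensor, and at a gauge the smaller of the two
  in-plane principal values (rosette gauges measure in-plane strain only).
* In-plane e1 orientation is the angle of the e1 axis measured
  counterclockwise from the gauge local +x axis.  A strain axis is 180
  degrees ambiguous; the reported representative is the direction vector
  returned by the half-angle formula theta = atan2(2 exy, exx - eyy) / 2,
  mapped into [0, 360).
* Shear components are tensor shears (eps_ij); sagittal = eps_xy,
  frontal = eps_xz, transverse = eps_yz in the anatomical frame
  (X superoinferior, Y anteroposterior, Z mediolateral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fe import StrainField
from .mesh import SurfacePatch, TetMesh, extract_surface

_ORTHO_TOL = 1e-9


@dataclass
class PrincipalStrains:
    """Sorted principal values (descending) and orthonormal axes."""

    values: np.ndarray  # (..., 3) with values[..., 0] >= values[..., 1] >= values[..., 2]
    axes: np.ndarray  # (..., 3, 3); axes[..., :, k] is the k-th principal direction

    @property
    def e1(self) -> np.ndarray:
        """Maximum principal strain."""
        return self.values[..., 0]

    @property
    def e_min(self) -> np.ndarray:
        """Minimum principal strain (the quantity reported as "e2")."""
        return self.values[..., 2]


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
        raise ValueError("rotation must be an orthonormal 3x3 matrix")
    return R


def tensor_to_matrix(t: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt (tensor shear) -> (..., 3, 3) symmetric matrices."""
    t = np.asarray(t, dtype=float)
    M = np.empty(t.shape[:-1] + (3, 3))
    M[..., 0, 0], M[..., 1, 1], M[..., 2, 2] = t[..., 0], t[..., 1], t[..., 2]
    M[..., 0, 1] = M[..., 1, 0] = t[..., 3]
    M[..., 0, 2] = M[..., 2, 0] = t[..., 4]
    M[..., 1, 2] = M[..., 2, 1] = t[..., 5]
    return M


def matrix_to_tensor(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M)
    return np.stack(
        [M[..., 0, 0], M[..., 1, 1], M[..., 2, 2], M[..., 0, 1], M[..., 0, 2], M[..., 1, 2]],
        axis=-1,
    )


def principal(t: np.ndarray) -> PrincipalStrains:
    """Principal strains of symmetric tensors given in Voigt (tensor-shear) form."""
    M = tensor_to_matrix(t)
    w, V = np.linalg.eigh(M)  # ascending
    order = [2, 1, 0]
    return PrincipalStrains(values=w[..., order], axes=V[..., :, order])


def rotate_tensor(t: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Components of the same strain state in the rotated frame: R eps R^T."""
    R = _check_rotation(R)
    M = tensor_to_matrix(t)
    return matrix_to_tensor(np.einsum("ij,...jk,lk->...il", R, M, R))


def shear_components(t: np.ndarray, frame: np.ndarray | None = None) -> np.ndarray:
    """Sagittal (xy), frontal (xz) and transverse (yz) tensor shears.

    ``frame`` rotates the tensor into the anatomical frame first; ``None``
    means the tensor is already anatomical.
    """
    if frame is not None:
        t = rotate_tensor(t, frame)
    t = np.asarray(t)
    return t[..., 3:6]


# ---------------------------------------------------------------------------
# Gauge sites
# ---------------------------------------------------------------------------

@dataclass
class GaugeSite:
    """A rosette strain-gauge site on the bone surface.

    ``rotation`` maps global coordinates into the gauge frame; the gauge
    plane is the local xy plane (local z is the surface normal).
    """

    name: str
    center: np.ndarray  # mm
    radius: float  # mm
    rotation: np.ndarray  # (3, 3) global -> gauge

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.rotation = _check_rotation(self.rotation)
        if not self.radius > 0:
            raise ValueError(f"gauge {self.name}: radius must be positive")


@dataclass
class GaugeReadout:
    """In-plane principal strains of the surface elements under one gauge."""

    site: str
    element_ids: np.ndarray
    e1: np.ndarray  # max in-plane principal, strain units of the input
    e_min: np.ndarray  # min in-plane principal
    orientation_deg: np.ndarray  # e1 axis angle in [0, 360)


def inplane_principal(exx: np.ndarray, eyy: np.ndarray, exy: np.ndarray):
    """2D principal values and e1 orientation (degrees in [0, 360))."""
    mean = 0.5 * (exx + eyy)
    r = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy**2)
    theta = np.degrees(0.5 * np.arctan2(2.0 * exy, exx - eyy))
    return mean + r, mean - r, np.mod(theta, 360.0)


def gauge_readout(
    mesh: TetMesh,
    strains: StrainField,
    site: GaugeSite,
    surface: SurfacePatch | None = None,
) -> GaugeReadout:
    """Rotate surface-element tensors under a gauge into its frame.

    Selects boundary faces whose centroid lies within ``site.radius`` of the
    gauge center, rotates each owning element's tensor into the gauge frame
    and returns the in-plane principal magnitudes and e1 orientations.
    """
    if surface is None:
        surface = extract_surface(mesh)
    d = np.linalg.norm(surface.face_centroids(mesh) - site.center, axis=1)
    hit = d <= site.radius
    if not hit.any():
        raise ValueError(
            f"gauge {site.name}: no surface faces within {site.radius} mm of the "
            "center — increase the patch radius"
        )
    owners = np.unique(surface.owners[hit])
    local = rotate_tensor(strains.tensor[owners], site.rotation)
    e1, e2, theta = inplane_principal(local[:, 0], local[:, 1], local[:, 3])
    return GaugeReadout(site=site.name, element_ids=owners, e1=e1, e_min=e2,
                        orientation_deg=theta)


# ---------------------------------------------------------------------------
# Differential maps and region summaries
# ---------------------------------------------------------------------------

DIFF_QUANTITIES = ("e1", "e_min", "e12", "e13", "e23")


@dataclass
class DifferentialMap:
    """Per-element difference a - b of one strain quantity between variants."""

    quantity: str
    pair: tuple[str, str]
    delta: np.ndarray  # (m,), units of the inputs

    def swapped(self) -> "DifferentialMap":
        return DifferentialMap(self.quantity, (self.pair[1], self.pair[0]), -self.delta)


def differential_map(
    a: np.ndarray,
    b: np.ndarray,
    quantity: str,
    pair: tuple[str, str] = ("a", "b"),
) -> DifferentialMap:
    """Element-wise a - b.  Principal quantities must be computed per model
    first and then differenced (never difference tensors and then take
    principals)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"field shapes differ: {a.shape} vs {b.shape} (same mesh required)")
    return DifferentialMap(quantity=quantity, pair=pair, delta=a - b)


@dataclass
class RegionSummary:
    """Descriptive statistics of one strain quantity over an element set."""

    region: str
    n: int
    mean: float
    sd: float  # sample SD (n - 1 divisor); 0 for a single element
    min: float
    max: float


def region_summary(values: np.ndarray, region_ids: np.ndarray, name: str = "") -> RegionSummary:
    region_ids = np.asarray(region_ids)
    if region_ids.size == 0:
        raise ValueError(f"region {name!r} is empty")
    v = np.asarray(values, dtype=float)[region_ids]
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return RegionSummary(region=name, n=int(v.size), mean=float(v.mean()), sd=sd,
                         min=float(v.min()), max=float(v.max()))
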