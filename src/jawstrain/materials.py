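"""Grayscale-to-elasticity calibration and region material assignment.

Cortical bone elasticity is mapped from CT grayscale (GV) through apparent
density by three affine calibration lines,

    rho = a + b * GV
    E   = e + f * rho        (MPa, floored at ``E_floor``)
    nu  = c + d * rho        (clamped to [``v_floor``, ``v_cap``])

with the density range optionally quantised into ``n_bins`` equal-width bins
(heterogeneous binned assignment; the density of each element is replaced by
its bin midpoint).  All other regions carry fixed isotropic properties, and
the periodontal-ligament (PDL) region is swapped between named stiffness
variants for the sensitivity analysis:

=========  ===========  ====
variant    PDL E (MPa)  nu
=========  ===========  ====
PDL        0.68         0.49
MODEL_1    0.07         0.49
MODEL_2    0.18         0.49
MODEL_3    13.8         0.49
MODEL_4    1750.0       0.49
NO_PDL     24500.0      0.49  (tooth properties — the ligament is "removed")
=========  ===========  ====
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .mesh import TetMesh


@dataclass(frozen=True)
class ElasticProps:
    """Isotropic elastic pair: Young's modulus E (MPa), Poisson's ratio v."""

    E: float
    v: float

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ValueError(f"E must be positive, got {self.E}")
        if not (0.0 < self.v < 0.5):
            raise ValueError(f"v must lie strictly in (0, 0.5), got {self.v}")


# fixed homogeneous properties of the non-cortical regions
TOOTH = ElasticProps(E=24_500.0, v=0.49)
TRABECULAR = ElasticProps(E=10_000.0, v=0.3)
SCREW = ElasticProps(E=105_000.0, v=0.36)

#: PDL-region properties per named variant
PDL_VARIANTS: dict[str, ElasticProps] = {
    "PDL": ElasticProps(E=0.68, v=0.49),
    "MODEL_1": ElasticProps(E=0.07, v=0.49),
    "MODEL_2": ElasticProps(E=0.18, v=0.49),
    "MODEL_3": ElasticProps(E=13.8, v=0.49),
    "MODEL_4": ElasticProps(E=1_750.0, v=0.49),
    "NO_PDL": TOOTH,
}


@dataclass
class CalibrationModel:
    """Affine GV->density->(E, v) calibration with clamps and binning.

    Defaults are the published theoretical-model coefficients for macaque
    mandibular cortical bone; the density line is read as intercept + slope.
    """

    density_intercept: float = -0.01979662
    density_slope: float = 1.0577433
    v_intercept: float = 0.400595880819907
    v_slope: float = -0.00000913165104192569
    E_intercept: float = -2.7501977952777819
    E_slope: float = 0.0082389155811676013
    E_floor: float = 50.0  # MPa; printed E(rho) line is negative at low density
    v_floor: float = 0.05
    v_cap: float = 0.49
    n_bins: int = 80

    def __post_init__(self) -> None:
        if not self.E_floor > 0:
            raise ValueError("E_floor must be positive")
        if not (0.0 < self.v_cap < 0.5):
            raise ValueError("v_cap must lie in (0, 0.5)")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    def density(self, gv):
        return self.density_intercept + self.density_slope * np.asarray(gv, dtype=float)

    def raw_E(self, rho):
        """E(rho) before the positivity floor, MPa."""
        return self.E_intercept + self.E_slope * np.asarray(rho, dtype=float)

    def raw_v(self, rho):
        """v(rho) before clamping."""
        return self.v_intercept + self.v_slope * np.asarray(rho, dtype=float)

    def props_from_density(self, rho) -> tuple[np.ndarray, np.ndarray]:
        E = np.maximum(self.E_floor, self.raw_E(rho))
        v = np.clip(self.raw_v(rho), self.v_floor, self.v_cap)
        return E, v

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)


def calibrate_element(gv: float, model: CalibrationModel) -> ElasticProps:
    """Elastic properties of a single element from its grayscale value."""
    if not np.isfinite(gv):
        raise ValueError(f"grayscale value must be finite, got {gv}")
    E, v = model.props_from_density(model.density(gv))
    return ElasticProps(E=float(E), v=float(v))


@dataclass
class MaterialField:
    """Per-element isotropic properties with the PDL-variant label."""

    E: np.ndarray  # (m,) MPa
    v: np.ndarray  # (m,) dimensionless
    variant_label: str = "custom"

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    def validate(self) -> None:
        if np.any(~(self.E > 0)) or np.any(~((self.v > 0) & (self.v < 0.5))):
            bad = np.flatnonzero(~((self.E > 0) & (self.v > 0) & (self.v < 0.5)))
            raise ValueError(f"invalid elastic properties on elements {bad[:5].tolist()}")

    def copy(self) -> "MaterialField":
        return MaterialField(self.E.copy(), self.v.copy(), self.variant_label)


def assign_cortical(
    mesh: TetMesh,
    gv_per_element: dict[int, float] | np.ndarray,
    model: CalibrationModel,
    binned: bool = True,
) -> MaterialField:
    """Calibrate the cortical region from grayscale; other regions get NaN.

    In binned mode the observed density range is split into ``model.n_bins``
    equal-width bins and each cortical element takes the properties of its
    bin midpoint, so E takes at most ``n_bins`` distinct values.  With a
    single bin every cortical element gets the mid-range density properties.
    """
    cortical = mesh.elements_in_region("cortical")
    if isinstance(gv_per_element, dict):
        missing = [int(e) for e in cortical if int(e) not in gv_per_element]
        if missing:
            raise ValueError(f"missing grayscale for cortical elements {missing[:10]}")
        gv = np.array([gv_per_element[int(e)] for e in cortical], dtype=float)
    else:
        gv_per_element = np.asarray(gv_per_element, dtype=float)
        if gv_per_element.shape[0] != mesh.n_elements:
            raise ValueError("gv array must have one value per element")
        gv = gv_per_element[cortical]
        if np.any(~np.isfinite(gv)):
            missing = cortical[~np.isfinite(gv)]
            raise ValueError(f"missing grayscale for cortical elements {missing[:10].tolist()}")

    rho = model.density(gv)
    if binned and rho.size:
        lo, hi = float(rho.min()), float(rho.max())
        if hi == lo:
            rho = np.full_like(rho, lo)
        else:
            width = (hi - lo) / model.n_bins
            idx = np.minimum((rho - lo) // width, model.n_bins - 1).astype(int)
            rho = lo + (idx + 0.5) * width

    E = np.full(mesh.n_elements, np.nan)
    v = np.full(mesh.n_elements, np.nan)
    E[cortical], v[cortical] = model.props_from_density(rho)
    return MaterialField(E=E, v=v, variant_label="cortical-only")


def make_variant(mesh: TetMesh, cortical: MaterialField, variant: str) -> MaterialField:
    """Complete a cortical field into a full per-element field for one variant."""
    if variant not in PDL_VARIANTS:
        raise ValueError(f"unknown PDL variant {variant!r}; choose one of {sorted(PDL_VARIANTS)}")
    out = cortical.copy()
    out.variant_label = variant
    for label, props in (
        ("tooth", TOOTH),
        ("trabecular", TRABECULAR),
        ("screw", SCREW),
        ("pdl", PDL_VARIANTS[variant]),
    ):
        ids = mesh.elements_in_region(label)
        out.E[ids] = props.E
        out.v[ids] = props.v
    out.validate()
    return out
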