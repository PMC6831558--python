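"""Model validation: FEM gauge strains against in-vivo strain-sample spreads.

A model passes a gauge/quantity check when its FEM median lies within the
boxplot whisker envelope [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the in-vivo cycle
samples (primary criterion), and, more loosely, within the full in-vivo
range.  Principal-strain orientations are compared on the circle: the
smallest arc covering the FEM orientations must lie inside the smallest arc
covering the in-vivo orientations.

Quartiles use linear interpolation between order statistics (the common
boxplot default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class InVivoSample:
    """Per-cycle gauge strains from the live animal (or a synthetic stand-in)."""

    gauge: str
    e1: np.ndarray  # microstrain, one per chewing cycle
    e_min: np.ndarray
    orientation_deg: np.ndarray  # in [0, 360)

    def __post_init__(self) -> None:
        self.e1 = np.asarray(self.e1, dtype=float)
        self.e_min = np.asarray(self.e_min, dtype=float)
        self.orientation_deg = np.mod(np.asarray(self.orientation_deg, dtype=float), 360.0)
        if self.e1.size < 4:
            raise ValueError(f"gauge {self.gauge}: need >= 4 cycles for quartiles")

    @property
    def n_cycles(self) -> int:
        return int(self.e1.size)


def whisker_bounds(sample: np.ndarray) -> tuple[float, float, float, float]:
    """(Q1, Q3, low, high) with low/high = Q1 -/+ 1.5 IQR beyond the box."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 4:
        raise ValueError(f"need >= 4 samples for quartiles, got {sample.size}")
    q1, q3 = np.percentile(sample, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    return float(q1), float(q3), float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


# ---------------------------------------------------------------------------
# Circular arcs for orientation ranges
# ---------------------------------------------------------------------------

def covering_arc(angles_deg: np.ndarray) -> tuple[float, float]:
    """Smallest arc (start_deg, width_deg) covering all angles on the circle."""
    a = np.sort(np.mod(np.asarray(angles_deg, dtype=float), 360.0))
    if a.size == 0:
        raise ValueError("empty angle sample")
    if a.size == 1:
        return float(a[0]), 0.0
    gaps = np.diff(np.append(a, a[0] + 360.0))
    k = int(np.argmax(gaps))
    start = a[(k + 1) % a.size]
    return float(start), float(360.0 - gaps[k])


def arc_contains(outer: tuple[float, float], inner: tuple[float, float]) -> bool:
    """True when arc ``inner`` lies entirely inside arc ``outer``."""
    if outer[1] >= 360.0:
        return True
    offset = np.mod(inner[0] - outer[0], 360.0)
    return bool(offset + inner[1] <= outer[1] + 1e-9)


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

@dataclass
class GaugeVerdict:
    """Validation verdicts of one model at one gauge."""

    gauge: str
    quantity: str  # "e1" | "e_min"
    fem_median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    invivo_min: float
    invivo_max: float
    within_whiskers: bool
    within_range: bool


@dataclass
class OrientationVerdict:
    gauge: str
    fem_arc: tuple[float, float]
    invivo_arc: tuple[float, float]
    within_range: bool


def validate_gauge(
    fem_e1: np.ndarray,
    fem_e_min: np.ndarray,
    fem_orientation_deg: np.ndarray,
    invivo: InVivoSample,
    gauge: str | None = None,
) -> tuple[list[GaugeVerdict], OrientationVerdict]:
    """Compare one model's gauge readout against the in-vivo sample."""
    if gauge is not None and gauge != invivo.gauge:
        raise ValueError(f"gauge name mismatch: FEM {gauge!r} vs in-vivo {invivo.gauge!r}")
    verdicts = []
    for quantity, fem, vivo in (("e1", fem_e1, invivo.e1), ("e_min", fem_e_min, invivo.e_min)):
        fem = np.asarray(fem, dtype=float)
        if fem.size == 0:
            raise ValueError(f"gauge {invivo.gauge}: empty FEM readout")
        med = float(np.median(fem))
        q1, q3, lo, hi = whisker_bounds(vivo)
        verdicts.append(
            GaugeVerdict(
                gauge=invivo.gauge, quantity=quantity, fem_median=med,
                q1=q1, q3=q3, whisker_low=lo, whisker_high=hi,
                invivo_min=float(vivo.min()), invivo_max=float(vivo.max()),
                within_whiskers=bool(lo <= med <= hi),
                within_range=bool(vivo.min() <= med <= vivo.max()),
            )
        )
    fem_arc = covering_arc(fem_orientation_deg)
    vivo_arc = covering_arc(invivo.orientation_deg)
    orient = OrientationVerdict(
        gauge=invivo.gauge, fem_arc=fem_arc, invivo_arc=vivo_arc,
        within_range=arc_contains(vivo_arc, fem_arc),
    )
    return verdicts, orient


def verdicts_to_frame(verdicts: list[GaugeVerdict]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in verdicts])


# ---------------------------------------------------------------------------
# CSV interface: columns gauge, cycle, e1, emin, theta
# ---------------------------------------------------------------------------

def read_invivo(path: str | Path) -> dict[str, InVivoSample]:
    df = pd.read_csv(path)
    required = {"gauge", "cycle", "e1", "emin", "theta"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for gauge, grp in df.groupby("gauge"):
        grp = grp.sort_values("cycle")
        out[str(gauge)] = InVivoSample(
            gauge=str(gauge), e1=grp["e1"].to_numpy(),
            e_min=grp["emin"].to_numpy(), orientation_deg=grp["theta"].to_numpy(),
        )
    return out


def write_invivo(samples: dict[str, InVivoSample], path: str | Path) -> None:
    rows = []
    for s in samples.values():
        for c in range(s.n_cycles):
            rows.append({"gauge": s.gauge, "cycle": c, "e1": s.e1[c],
                         "emin": s.e_min[c], "theta": s.orientation_deg[c]})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
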