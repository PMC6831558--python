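"""Muscle-force vectors and constraint schemes for simulated unilateral chewing.

Each jaw-elevator muscle contributes a force of magnitude

    |F| = PCSA (cm^2) * specific tension (30 N/cm^2) * normalized EMG,

directed from the centroid of its mandibular insertion node set toward its
cranial attachment point, and split equally over the insertion nodes.

Anatomical frame convention (configurable downstream): X = superoinferior,
Y = anteroposterior, Z = mediolateral; the sagittal, frontal and transverse
planes are then XY, XZ and YZ.

Constraint scenarios:

* ``chewing`` — occlusal surfaces of the working-side bite teeth fixed in
  all directions (the bite force emerges as their reaction); one node atop
  the working condyle fixed in all directions; one node atop the balancing
  condyle fixed superoinferiorly and anteroposteriorly but free to translate
  mediolaterally (allows lateral transverse bending).
* ``overconstrained`` — both condyle nodes fixed in all three directions.
* ``clenching-scaled`` — chewing constraints with a user-supplied table of
  replacement EMG scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TetMesh

logger = logging.getLogger(__name__)

SPECIFIC_TENSION = 30.0  # N/cm^2, muscle-specific tension estimate

AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}
SUPEROINFERIOR, ANTEROPOSTERIOR, MEDIOLATERAL = "X", "Y", "Z"

SCENARIOS = ("chewing", "overconstrained", "clenching-scaled")


@dataclass
class MuscleDef:
    """One muscle: PCSA in cm^2, EMG scale in [0, 1], attachment geometry."""

    name: str
    side: str  # "working" | "balancing"
    pcsa: float
    emg_scale: float
    origin_point: np.ndarray  # cranial attachment, mm
    insertion_nodes: str  # node-set name on the mandible

    def __post_init__(self) -> None:
        self.origin_point = np.asarray(self.origin_point, dtype=float).reshape(3)
        if not self.pcsa > 0:
            raise ValueError(f"muscle {self.name}: pcsa must be positive")
        if not (0.0 <= self.emg_scale <= 1.0):
            raise ValueError(f"muscle {self.name}: emg_scale must lie in [0, 1]")


@dataclass
class ConstraintSpec:
    """Zero-displacement constraint on a node set along the listed axes."""

    node_set: str
    fixed_axes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.fixed_axes = tuple(self.fixed_axes)
        if not self.fixed_axes:
            raise ValueError("at least one axis must be fixed")
        unknown = set(self.fixed_axes) - set(AXIS_INDEX)
        if unknown:
            raise ValueError(f"unknown axes {sorted(unknown)}")


@dataclass
class LoadCase:
    """Nodal force vectors plus constraint specs for one solve."""

    nodal_forces: dict[int, np.ndarray]
    constraints: list[ConstraintSpec]
    scenario_label: str = "chewing"
    muscle_totals: dict[str, np.ndarray] = field(default_factory=dict)

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros((n_nodes, 3))
        for node, vec in self.nodal_forces.items():
            f[node] += vec
        return f

    def fixed_dof_mask(self, mesh: TetMesh) -> np.ndarray:
        fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
        for c in self.constraints:
            try:
                nodes = mesh.node_sets[c.node_set]
            except KeyError:
                raise KeyError(f"mesh has no node set {c.node_set!r}") from None
            for ax in c.fixed_axes:
                fixed[nodes, AXIS_INDEX[ax]] = True
        return fixed

    def sanitize(self, mesh: TetMesh) -> None:
        """Zero (with a warning) force components applied along fixed axes."""
        fixed = self.fixed_dof_mask(mesh)
        for node, vec in self.nodal_forces.items():
            clash = fixed[node] & (vec != 0.0)
            if clash.any():
                logger.warning(
                    "node %d: zeroing force component(s) %s applied along fixed axes",
                    node,
                    [a for a, c in zip("XYZ", clash) if c],
                )
                vec[clash] = 0.0


def muscle_force(
    m: MuscleDef,
    mesh: TetMesh,
    specific_tension: float = SPECIFIC_TENSION,
) -> np.ndarray:
    """Total force vector (N) of one muscle.

    Magnitude = pcsa * specific_tension * emg_scale; direction is the unit
    vector from the insertion-node centroid toward the cranial origin.
    """
    try:
        nodes = mesh.node_sets[m.insertion_nodes]
    except KeyError:
        raise KeyError(f"mesh has no node set {m.insertion_nodes!r} (muscle {m.name})") from None
    if nodes.size == 0:
        raise ValueError(f"muscle {m.name}: insertion node set is empty")
    centroid = mesh.nodes[nodes].mean(axis=0)
    d = m.origin_point - centroid
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError(f"muscle {m.name}: origin coincides with insertion centroid")
    return m.pcsa * specific_tension * m.emg_scale * d / norm


def distribute_force(total: np.ndarray, insertion_nodes: np.ndarray) -> dict[int, np.ndarray]:
    """Equal per-node split of a total force vector."""
    insertion_nodes = np.asarray(insertion_nodes)
    if insertion_nodes.size == 0:
        raise ValueError("cannot distribute a force over an empty node list")
    per = np.asarray(total, dtype=float) / insertion_nodes.size
    return {int(n): per.copy() for n in insertion_nodes}


def build_chewing_case(
    mesh: TetMesh,
    muscles: list[MuscleDef],
    scenario: str = "chewing",
    emg_override: dict[str, float] | None = None,
    specific_tension: float = SPECIFIC_TENSION,
) -> LoadCase:
    """Assemble the nodal loads and constraints of one chewing simulation."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose one of {SCENARIOS}")
    for required in ("bite_occlusal", "condyle_working", "condyle_balancing"):
        if required not in mesh.node_sets:
            raise KeyError(f"mesh is missing required node set {required!r}")

    if scenario == "clenching-scaled":
        if emg_override is None:
            raise ValueError("clenching-scaled scenario requires an emg_override table")
        muscles = [
            MuscleDef(m.name, m.side, m.pcsa, emg_override.get(m.name, m.emg_scale),
                      m.origin_point, m.insertion_nodes)
            for m in muscles
        ]

    nodal: dict[int, np.ndarray] = {}
    totals: dict[str, np.ndarray] = {}
    for m in muscles:
        total = muscle_force(m, mesh, specific_tension)
        totals[m.name] = total
        for node, vec in distribute_force(total, mesh.node_sets[m.insertion_nodes]).items():
            nodal[node] = nodal.get(node, np.zeros(3)) + vec

    if scenario == "overconstrained":
        condyle_constraints = [
            ConstraintSpec("condyle_working", ("X", "Y", "Z")),
            ConstraintSpec("condyle_balancing", ("X", "Y", "Z")),
        ]
    else:
        condyle_constraints = [
            ConstraintSpec("condyle_working", ("X", "Y", "Z")),
            # balancing condyle: mediolateral (Z) translation left free
            ConstraintSpec("condyle_balancing", (SUPEROINFERIOR, ANTEROPOSTERIOR)),
        ]
    constraints = [ConstraintSpec("bite_occlusal", ("X", "Y", "Z"))] + condyle_constraints

    case = LoadCase(nodal_forces=nodal, constraints=constraints,
                    scenario_label=scenario, muscle_totals=totals)
    case.sanitize(mesh)
    return case


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

MUSCLE_COLUMNS = ["name", "side", "pcsa_cm2", "emg_scale",
                  "origin_x", "origin_y", "origin_z", "insertion_set"]


def read_muscles(path: str | Path) -> list[MuscleDef]:
    df = pd.read_csv(path)
    missing = set(MUSCLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing muscle columns {sorted(missing)}")
    return [
        MuscleDef(
            name=row["name"], side=row["side"], pcsa=float(row["pcsa_cm2"]),
            emg_scale=float(row["emg_scale"]),
            origin_point=np.array([row["origin_x"], row["origin_y"], row["origin_z"]], dtype=float),
            insertion_nodes=row["insertion_set"],
        )
        for _, row in df.iterrows()
    ]


def write_muscles(muscles: list[MuscleDef], path: str | Path) -> None:
    rows = [
        {
            "name": m.name, "side": m.side, "pcsa_cm2": m.pcsa, "emg_scale": m.emg_scale,
            "origin_x": m.origin_point[0], "origin_y": m.origin_point[1],
            "origin_z": m.origin_point[2], "insertion_set": m.insertion_nodes,
        }
        for m in muscles
    ]
    pd.DataFrame(rows, columns=MUSCLE_COLUMNS).to_csv(path, index=False, float_format="%.10g")
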