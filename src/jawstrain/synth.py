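"""Synthetic inputs: mandible phantom, grayscale field, muscles, gauges, in-vivo data.

The phantom is a deterministic, structured-extruded stand-in for a CT-derived
mandible: a curved-beam corpus (a circular arc swept cross-section in the
anatomical frame X = superoinferior, Y = anteroposterior, Z = mediolateral,
open end posterior) with one condylar post at each end, and per-side tooth
sockets cut into the occlusal surface.  Each socket holds a tooth block
wrapped — when ``pdl_thickness >= 3`` — by a conforming periodontal-ligament
shell exactly ``pdl_thickness`` element layers thick on its sides and floor
(automatic non-manifold meshing of the real tissue space requires a minimum
thickness of 3 voxels, which the phantom honours as 3 element layers).
Hexahedral lattice cells are split into 6 tetrahedra each (Kuhn
triangulation), which keeps faces conforming across every cell, so adjacent
regions are tied simply by sharing nodes.

The left (+Z) side is the working side.  All outputs are deterministic given
the spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .loads import MuscleDef
from .mesh import MeshError, TetMesh
from .strain import GaugeSite
from .validation import InVivoSample

# paths from hex corner (0,0,0) to (1,1,1): the 6 Kuhn tets of a cell
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the mandible phantom (lengths in mm).

    ``pdl_thickness`` counts element layers between tooth and bone: 0 means
    the tooth block is fused directly to the socket, otherwise at least 3
    layers are required.
    """

    corpus_length: float = 100.0  # arc length of the corpus midline
    corpus_height: float = 12.0  # superoinferior cross-section size
    corpus_width: float = 14.0  # radial (thickness) cross-section size
    arch_radius: float = 29.0  # radius of curvature of the midline
    n_sockets_per_side: int = 3
    socket_width: float = 3.75  # tooth-block width (both horizontal axes)
    socket_depth: float = 3.75  # tooth-block depth below the occlusal surface
    bite_sockets: int = 1  # anterior working-side teeth with constrained occlusal surfaces
    pdl_thickness: int = 3  # element layers; 0 = no PDL shell
    edge_length: float = 1.25  # target element edge, mm
    post_height: float = 7.5  # condylar post height above the occlusal plane
    post_width: float = 6.0  # arc-length footprint of each post
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pdl_thickness != 0 and self.pdl_thickness < 3:
            raise ValueError("pdl_thickness must be 0 (no PDL) or >= 3 layers")
        for name in ("corpus_length", "corpus_height", "corpus_width", "arch_radius",
                     "socket_width", "socket_depth", "edge_length", "post_height",
                     "post_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sockets_per_side < 1:
            raise ValueError("need at least one socket per side")
        if not (1 <= self.bite_sockets <= self.n_sockets_per_side):
            raise ValueError("bite_sockets must lie in [1, n_sockets_per_side]")

    # -- derived lattice dimensions -------------------------------------
    @property
    def counts(self) -> dict[str, int]:
        e = self.edge_length
        n_s = max(4, round(self.corpus_length / e))
        n_u = max(2, round(self.corpus_width / e))
        n_v = max(2, round(self.corpus_height / e))
        t_s = max(1, round(self.socket_width / (self.corpus_length / n_s)))
        t_u = max(1, round(self.socket_width / (self.corpus_width / n_u)))
        t_v = max(1, round(self.socket_depth / (self.corpus_height / n_v)))
        w_post = max(2, round(self.post_width / (self.corpus_length / n_s)))
        n_post = max(2, round(self.post_height / (self.corpus_height / n_v)))
        return dict(n_s=n_s, n_u=n_u, n_v=n_v, t_s=t_s, t_u=t_u, t_v=t_v,
                    w_post=w_post, n_post=n_post)

    def analytic_volume(self) -> float:
        """Exact volume (mm^3) of the parametric solid (corpus + posts)."""
        c = self.counts
        phi = self.corpus_length / self.arch_radius
        dphi = phi / c["n_s"]
        corpus = self.arch_radius * self.corpus_width * phi * self.corpus_height
        post_h = c["n_post"] * (self.corpus_height / c["n_v"])
        posts = 2 * self.arch_radius * self.corpus_width * (c["w_post"] * dphi) * post_h
        return corpus + posts

    def meshing_tolerance(self) -> float:
        """Relative volume defect of the straight-edge mesh vs the curved solid."""
        c = self.counts
        dphi = (self.corpus_length / self.arch_radius) / c["n_s"]
        return 1.0 - math.sin(dphi) / dphi + 1e-12


def _layout_thickness(spec: PhantomSpec) -> int:
    # socket layout always reserves a 3-layer shell so the pdl_thickness=0
    # twin is geometry- and layout-matched to its >=3 sibling
    return spec.pdl_thickness if spec.pdl_thickness > 0 else 3


def _socket_slots(spec: PhantomSpec) -> tuple[list[tuple[int, int]], dict]:
    """Per-socket s-cell start indices for the working (left, high s) side,
    mirrored for the balancing side.  Returns [(side, s0), ...]."""
    c = spec.counts
    p = _layout_thickness(spec)
    w_s = c["t_s"] + 2 * p
    n_s, w_post = c["n_s"], c["w_post"]
    half = n_s // 2
    front_margin = max(2, c["t_s"])
    lo = half + front_margin
    hi = n_s - w_post - 1  # leave one cortical column before the post
    avail = hi - lo
    need = spec.n_sockets_per_side * w_s + (spec.n_sockets_per_side - 1)
    if avail < need:
        # the admissible edge scales inversely with cell demand along the arc
        max_edge = spec.edge_length * avail / need
        raise MeshError(
            f"edge length {spec.edge_length} mm too coarse for {spec.n_sockets_per_side} "
            f"sockets with a {p}-layer PDL shell along the arc; use edge_length <= "
            f"{max_edge:.3g} mm or fewer/narrower sockets"
        )
    gap = (avail - spec.n_sockets_per_side * w_s) // max(1, spec.n_sockets_per_side)
    slots = []
    for k in range(spec.n_sockets_per_side):
        s0 = lo + k * (w_s + gap)
        slots.append(("working", s0))
        # mirror across the arc midline
        slots.append(("balancing", n_s - (s0 + w_s)))
    return slots, c


def _check_cross_section(spec: PhantomSpec) -> None:
    c = spec.counts
    p = _layout_thickness(spec)
    w_u = c["t_u"] + 2 * p
    if w_u + 2 > c["n_u"]:
        max_edge = spec.corpus_width / (w_u + 2)
        raise MeshError(
            f"corpus width {spec.corpus_width} mm cannot hold a {p}-layer PDL shell at "
            f"edge length {spec.edge_length} mm; use edge_length <= {max_edge:.3g} mm"
        )
    h_sock = c["t_v"] + p
    if h_sock + 3 > c["n_v"]:
        max_edge = spec.corpus_height / (h_sock + 3)
        raise MeshError(
            f"corpus height {spec.corpus_height} mm too shallow for the socket plus "
            f"PDL floor at edge length {spec.edge_length} mm; use edge_length <= "
            f"{max_edge:.3g} mm"
        )


def make_phantom(spec: PhantomSpec) -> TetMesh:
    """Build the mandible phantom mesh with all regions and named sets."""
    _check_cross_section(spec)
    slots, c = _socket_slots(spec)
    n_s, n_u, n_v = c["n_s"], c["n_u"], c["n_v"]
    t_s, t_u, t_v = c["t_s"], c["t_u"], c["t_v"]
    w_post, n_post = c["w_post"], c["n_post"]
    p = _layout_thickness(spec)
    has_pdl = spec.pdl_thickness > 0
    w_s, w_u = t_s + 2 * p, t_u + 2 * p
    h_sock = t_v + p

    phi_total = spec.corpus_length / spec.arch_radius
    du = spec.corpus_width / n_u
    dv = spec.corpus_height / n_v

    def node_pos(i_s: int, i_u: int, i_v: int) -> tuple[float, float, float]:
        phi = (i_s / n_s - 0.5) * phi_total
        r = spec.arch_radius + (i_u - n_u / 2) * du
        return (i_v * dv, r * math.cos(phi), r * math.sin(phi))

    # ---- cell classification -----------------------------------------
    u0 = (n_u - w_u) // 2  # socket footprint start in u (centred)
    socket_cells: dict[tuple[int, int, int], str] = {}
    tooth_tags: dict[tuple[int, int, int], tuple[str, int]] = {}
    footprints: list[tuple[str, int, int]] = []  # (side, s0, socket_index)
    per_side_index: dict[str, int] = {"working": 0, "balancing": 0}
    for side, s0 in slots:
        idx = per_side_index[side]
        per_side_index[side] += 1
        footprints.append((side, s0, idx))
        for ds_ in range(w_s):
            for du_ in range(w_u):
                for dv_ in range(h_sock):
                    cell = (s0 + ds_, u0 + du_, n_v - 1 - dv_)
                    in_tooth = (p <= ds_ < p + t_s and p <= du_ < p + t_u and dv_ < t_v)
                    if in_tooth:
                        socket_cells[cell] = "tooth"
                        tooth_tags[cell] = (side, idx)
                    elif has_pdl:
                        socket_cells[cell] = "pdl"

    # screws: two single cells on the outer surface at the front midline
    screw_cells = {(n_s // 2 - 2, n_u - 1, n_v // 2), (n_s // 2 + 2, n_u - 1, n_v // 2)}
    screw_cells = {cell for cell in screw_cells if cell not in socket_cells}

    trab_top = n_v - h_sock - 1  # keep a cortical floor below every socket

    def classify(i_s: int, i_u: int, i_v: int) -> str:
        cell = (i_s, i_u, i_v)
        if cell in socket_cells:
            return socket_cells[cell]
        if cell in screw_cells:
            return "screw"
        if (1 <= i_s < n_s - 1 and 1 <= i_u < n_u - 1 and 1 <= i_v < trab_top):
            return "trabecular"
        return "cortical"

    # ---- build cells: corpus + posts ---------------------------------
    cells: list[tuple[int, int, int]] = [
        (i_s, i_u, i_v) for i_s in range(n_s) for i_u in range(n_u) for i_v in range(n_v)
    ]
    post_ranges = {"balancing": range(0, w_post), "working": range(n_s - w_post, n_s)}
    for rng_ in post_ranges.values():
        cells.extend(
            (i_s, i_u, i_v)
            for i_s in rng_ for i_u in range(n_u) for i_v in range(n_v, n_v + n_post)
        )

    node_index: dict[tuple[int, int, int], int] = {}
    coords: list[tuple[float, float, float]] = []

    def node(i_s: int, i_u: int, i_v: int) -> int:
        key = (i_s, i_u, i_v)
        idx = node_index.get(key)
        if idx is None:
            idx = len(coords)
            node_index[key] = idx
            coords.append(node_pos(*key))
        return idx

    tets: list[list[int]] = []
    region: list[str] = []
    cell_of_tet: list[tuple[int, int, int]] = []
    for (i_s, i_u, i_v) in cells:
        corner = {}
        for d in range(8):
            di, dj, dk = d & 1, (d >> 1) & 1, (d >> 2) & 1
            corner[(di, dj, dk)] = node(i_s + di, i_u + dj, i_v + dk)
        label = classify(i_s, i_u, i_v) if i_v < n_v else "cortical"
        for perm in _KUHN_PERMS:
            path = [(0, 0, 0)]
            cur = [0, 0, 0]
            for ax in perm:
                cur[ax] = 1
                path.append(tuple(cur))
            tet = [corner[q] for q in path]
            tets.append(tet)
            region.append(label)
            cell_of_tet.append((i_s, i_u, i_v))

    nodes = np.asarray(coords, dtype=float)
    tets_arr = np.asarray(tets, dtype=np.int64)
    # enforce positive signed volumes (the Kuhn split alternates handedness)
    pcoord = nodes[tets_arr]
    vol = np.einsum("ij,ij->i",
                    np.cross(pcoord[:, 1] - pcoord[:, 0], pcoord[:, 2] - pcoord[:, 0]),
                    pcoord[:, 3] - pcoord[:, 0])
    neg = np.flatnonzero(vol < 0)
    tets_arr[neg[:, None], [2, 3]] = tets_arr[neg[:, None], [3, 2]]

    mesh = TetMesh(nodes=nodes, tets=tets_arr, region=np.asarray(region, dtype="U16"))

    # ---- element sets -------------------------------------------------
    cell_arr = np.asarray(cell_of_tet)
    elem_sets: dict[str, list[int]] = {"alveolar_surface": [], "tooth_root": []}
    alveolar_cells = set()
    for side, s0, idx in footprints:
        for i_s in range(s0 - 2, s0 + w_s + 2):
            for i_u in range(u0 - 2, u0 + w_u + 2):
                for i_v in range(max(0, trab_top), n_v):
                    alveolar_cells.add((i_s, i_u, i_v))
    root_top = n_v - 1 - t_v // 2  # lower half of each tooth block
    for e in range(mesh.n_elements):
        cell = tuple(cell_arr[e])
        if region[e] == "cortical" and cell in alveolar_cells:
            elem_sets["alveolar_surface"].append(e)
        if region[e] == "tooth" and cell[2] <= root_top:
            elem_sets["tooth_root"].append(e)

    # ---- node sets ----------------------------------------------------
    node_sets: dict[str, list[int]] = {}

    def add_nodes(name: str, pred) -> None:
        ids = [i for key, i in node_index.items() if pred(*key)]
        node_sets[name] = sorted(set(node_sets.get(name, []) + ids))

    # occlusal surfaces of the anterior working-side bite teeth (the jaw
    # chews on a minority of its teeth; the rest ride free in their sockets)
    bite_slots = sorted(
        [s0 for side, s0, idx in footprints if side == "working"]
    )[: spec.bite_sockets]
    for s0 in bite_slots:
        add_nodes("bite_occlusal",
                  lambda i_s, i_u, i_v, s0=s0: (
                      i_v == n_v
                      and s0 + p <= i_s <= s0 + p + t_s
                      and u0 + p <= i_u <= u0 + p + t_u))

    top = n_v + n_post
    node_sets["condyle_working"] = [node_index[(n_s - w_post // 2 - 1, n_u // 2, top)]]
    node_sets["condyle_balancing"] = [node_index[(w_post // 2, n_u // 2, top)]]

    sides = {"working": dict(post=range(n_s - w_post, n_s + 1),
                             corpus_s=range(n_s - w_post - 6, n_s - w_post + 1)),
             "balancing": dict(post=range(0, w_post + 1),
                               corpus_s=range(w_post, w_post + 7))}
    for side, rngs in sides.items():
        tag = "w" if side == "working" else "b"
        add_nodes(f"ins_masseter_superficial_{tag}",
                  lambda i_s, i_u, i_v, r=rngs["corpus_s"]: (
                      i_u == n_u and i_s in r and n_v - 3 <= i_v <= n_v))
        add_nodes(f"ins_masseter_deep_{tag}",
                  lambda i_s, i_u, i_v, r=rngs["post"]: (
                      i_u == n_u and i_s in r and n_v <= i_v <= n_v + 2))
        # skip the u = n_u // 2 row so insertions never touch the condyle node
        add_nodes(f"ins_temporalis_anterior_{tag}",
                  lambda i_s, i_u, i_v, r=rngs["post"]: (
                      i_v == top and i_s in r and i_u < n_u // 2))
        add_nodes(f"ins_temporalis_posterior_{tag}",
                  lambda i_s, i_u, i_v, r=rngs["post"]: (
                      i_v == top and i_s in r and i_u > n_u // 2))
        add_nodes(f"ins_pterygoid_medial_{tag}",
                  lambda i_s, i_u, i_v, r=rngs["corpus_s"]: (
                      i_u == 0 and i_s in r and 0 <= i_v <= 3))

    mesh.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in node_sets.items()}
    mesh.element_sets = {k: np.asarray(sorted(v), dtype=np.int64) for k, v in elem_sets.items()}
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Default muscles and gauges for the phantom
# ---------------------------------------------------------------------------

#: synthetic PCSA (cm^2) and normalized EMG scales at peak working-side bone
#: strain; plausible for an adult macaque but NOT the unpublished subject data
_MUSCLE_TABLE = [
    # name, pcsa, emg_working, emg_balancing
    ("masseter_superficial", 3.0, 0.95, 0.55),
    ("masseter_deep", 1.2, 0.90, 0.50),
    ("temporalis_anterior", 2.8, 0.90, 0.50),
    ("temporalis_posterior", 1.6, 0.85, 0.45),
    ("pterygoid_medial", 1.9, 0.85, 0.60),
]


def default_muscles(spec: PhantomSpec) -> list[MuscleDef]:
    """The 10-muscle table (5 per side) matching the phantom's insertion sets."""
    c = spec.counts
    phi_total = spec.corpus_length / spec.arch_radius
    top_x = spec.corpus_height + c["n_post"] * (spec.corpus_height / c["n_v"])

    def arm_phi(side: str, back: float) -> float:
        # angular position near the posterior end of each arm
        s_frac = 1.0 - back if side == "working" else back
        return (s_frac - 0.5) * phi_total

    muscles = []
    for side, tag in (("working", "w"), ("balancing", "b")):
        for name, pcsa, emg_w, emg_b in _MUSCLE_TABLE:
            emg = emg_w if side == "working" else emg_b
            phi = arm_phi(side, 0.08)
            r_out = spec.arch_radius + spec.corpus_width  # lateral of the corpus
            r_in = spec.arch_radius - spec.corpus_width  # medial of the corpus
            if name.startswith("masseter"):
                origin = (top_x + 18.0, r_out * math.cos(phi), r_out * math.sin(phi))
            elif name.startswith("temporalis"):
                back = 0.02 if name.endswith("anterior") else -0.04
                phi2 = arm_phi(side, 0.08 + back)
                origin = (top_x + 30.0, spec.arch_radius * math.cos(phi2),
                          spec.arch_radius * math.sin(phi2))
            else:  # medial pterygoid pulls up and medially
                origin = (top_x + 15.0, r_in * math.cos(phi), r_in * math.sin(phi))
            muscles.append(
                MuscleDef(name=f"{name}_{tag}", side=side, pcsa=pcsa, emg_scale=emg,
                          origin_point=np.asarray(origin),
                          insertion_nodes=f"ins_{name}_{tag}")
            )
    return muscles


def default_gauges(spec: PhantomSpec, radius: float | None = None) -> list[GaugeSite]:
    """Three rosette sites on the working-side corpus: ULAT, LLAT (lateral
    surface, upper / lower) and MED (medial surface)."""
    c = spec.counts
    slots, _ = _socket_slots(spec)
    s0 = min(s for side, s in slots if side == "working")
    phi_total = spec.corpus_length / spec.arch_radius
    p = _layout_thickness(spec)
    s_center = s0 + (c["t_s"] + 2 * p) / 2.0
    phi = (s_center / c["n_s"] - 0.5) * phi_total
    if radius is None:
        radius = 2.5 * spec.edge_length

    r_out = spec.arch_radius + spec.corpus_width / 2.0
    r_in = spec.arch_radius - spec.corpus_width / 2.0

    def site(name: str, r: float, x: float, outward: float) -> GaugeSite:
        center = np.array([x, r * math.cos(phi), r * math.sin(phi)])
        normal = outward * np.array([0.0, math.cos(phi), math.sin(phi)])
        ex = np.array([0.0, -math.sin(phi), math.cos(phi)])  # arch tangent
        ey = np.cross(normal, ex)
        R = np.vstack([ex, ey, normal])  # rows: gauge axes in global coords
        return GaugeSite(name=name, center=center, radius=radius, rotation=R)

    h = spec.corpus_height
    return [
        site("ULAT", r_out, 0.65 * h, +1.0),
        site("LLAT", r_out, 0.25 * h, +1.0),
        site("MED", r_in, 0.45 * h, -1.0),
    ]


# ---------------------------------------------------------------------------
# Grayscale field
# ---------------------------------------------------------------------------

def make_grayscale(
    mesh: TetMesh,
    seed: int = 0,
    gv_range: tuple[float, float] = (1.6e6, 2.2e6),
    noise: float = 0.05,
    constant: float | None = None,
) -> np.ndarray:
    """Smooth synthetic grayscale over cortical elements (NaN elsewhere).

    A low-order spatial polynomial plus bounded uniform noise, min-max mapped
    onto ``gv_range``.  The default range is chosen so the published
    calibration yields cortical stiffness in the 13–18 GPa band.  With
    ``constant`` set, every cortical element gets that value.
    """
    gv = np.full(mesh.n_elements, np.nan)
    cortical = mesh.elements_in_region("cortical")
    if cortical.size == 0:
        raise ValueError("mesh has no cortical region")
    if constant is not None:
        gv[cortical] = float(constant)
        return gv
    X = mesh.element_centroids()[cortical]
    lo, hi = X.min(axis=0), X.max(axis=0)
    T = (X - lo) / np.where(hi - lo > 0, hi - lo, 1.0)
    base = 0.55 + 0.3 * T[:, 0] - 0.2 * T[:, 2] + 0.25 * T[:, 1] * T[:, 0] - 0.15 * T[:, 1] ** 2
    rng = np.random.default_rng(seed)
    field = base + noise * rng.uniform(-1.0, 1.0, size=base.size)
    fmin, fmax = field.min(), field.max()
    unit = (field - fmin) / (fmax - fmin if fmax > fmin else 1.0)
    gv[cortical] = gv_range[0] + unit * (gv_range[1] - gv_range[0])
    return gv


# ---------------------------------------------------------------------------
# Synthetic in-vivo samples
# ---------------------------------------------------------------------------

def _planted_quantity(n: int, median: float, iqr: float, vmin: float, vmax: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Sample whose empirical quartiles converge to the planted values.

    Draws uniforms and maps them through the piecewise-linear inverse CDF
    anchored at (0, vmin), (0.25, Q1), (0.5, median), (0.75, Q3), (1, vmax).
    """
    if iqr < 0 or vmax < vmin:
        raise ValueError("invalid plant: negative IQR or empty range")
    q1, q3 = median - iqr / 2.0, median + iqr / 2.0
    if q1 < vmin or q3 > vmax or (vmax - vmin) < iqr:
        raise ValueError(
            f"infeasible plant: range [{vmin}, {vmax}] cannot contain the "
            f"quartile box [{q1}, {q3}]"
        )
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, [0.0, 0.25, 0.5, 0.75, 1.0], [vmin, q1, median, q3, vmax])


def make_invivo(
    gauge: str,
    n: int,
    e1_plant: dict[str, float],
    emin_plant: dict[str, float],
    orientation_arc: tuple[float, float],
    seed: int = 0,
) -> InVivoSample:
    """Synthetic per-cycle gauge sample with planted median/IQR/range.

    Each plant is a dict with keys ``median``, ``iqr``, ``min``, ``max``;
    ``orientation_arc`` is (start_deg, width_deg) and all generated
    orientations fall inside it.
    """
    if n < 4:
        raise ValueError("need n >= 4 cycles")
    rng = np.random.default_rng(seed)
    e1 = _planted_quantity(n, e1_plant["median"], e1_plant["iqr"],
                           e1_plant["min"], e1_plant["max"], rng)
    emin = _planted_quantity(n, emin_plant["median"], emin_plant["iqr"],
                             emin_plant["min"], emin_plant["max"], rng)
    start, width = orientation_arc
    theta = np.mod(start + rng.uniform(0.0, 1.0, size=n) * width, 360.0)
    return InVivoSample(gauge=gauge, e1=e1, e_min=emin, orientation_deg=theta)
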