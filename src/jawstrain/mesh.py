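"""Tetrahedral mesh container, region/set bookkeeping and I/O.

All other modules operate on :class:`TetMesh`: linear 4-node tetrahedra with
named element regions (``cortical``, ``trabecular``, ``tooth``, ``pdl``,
``screw``), plus arbitrary named node and element sets.  Coordinates are in
millimetres.  Internally everything is contiguous 0-based; the Abaqus-INP
dialect's 1-based ids are remapped on read and restored on write.

Supported formats:

* Abaqus-INP subset — only ``*NODE``, ``*ELEMENT, TYPE=C3D4``, ``*NSET`` and
  ``*ELSET`` keywords; anything else is skipped with a logged warning.
* Native JSON — a direct, documented serialisation of the container.
* Legacy ASCII VTK unstructured grid — write (with per-element scalar
  fields) and a minimal reader used for round-trip verification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

REGION_LABELS = ("cortical", "trabecular", "tooth", "pdl", "screw")

# local node indices of the 4 faces of a tet, outward under positive volume
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class MeshError(ValueError):
    """Raised for malformed meshes or mesh files."""


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with named regions and sets.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) int array of node indices; positive signed volume ordering
    region : (m,) array of region labels (unicode)
    node_sets : name -> sorted int array of node indices
    element_sets : name -> sorted int array of element indices
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.region = np.asarray(self.region, dtype="U16")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.element_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.element_sets.items()}

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def signed_volumes(self) -> np.ndarray:
        """Per-element signed volume (mm^3); positive under the ordering convention."""
        p = self.nodes[self.tets]
        return np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        ) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def elements_in_region(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)

    def validate(self) -> None:
        """Check every container invariant; raise :class:`MeshError` on failure."""
        m, n = self.n_elements, self.n_nodes
        if self.region.shape != (m,):
            raise MeshError(f"region array has length {self.region.shape}, expected {m}")
        if self.tets.min(initial=0) < 0 or (m and self.tets.max() >= n):
            bad = np.flatnonzero((self.tets < 0).any(axis=1) | (self.tets >= n).any(axis=1))
            raise MeshError(f"elements {bad[:5].tolist()} reference nonexistent node ids")
        for e in range(m):
            if len(set(self.tets[e])) != 4:
                raise MeshError(f"element {e} has repeated node ids {self.tets[e].tolist()}")
        vol = self.signed_volumes()
        if m and vol.min() <= 0.0:
            bad = np.flatnonzero(vol <= 0.0)
            raise MeshError(
                f"{bad.size} elements have non-positive signed volume (first: element "
                f"{bad[0]}, volume {vol[bad[0]]:.3g} mm^3)"
            )
        unknown = set(np.unique(self.region)) - set(REGION_LABELS)
        if unknown:
            raise MeshError(f"unknown region labels {sorted(unknown)}")
        for name, ids in self.node_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= n):
                raise MeshError(f"node set {name!r} references nonexistent nodes")
        for name, ids in self.element_sets.items():
            if ids.size and (ids.min() < 0 or ids.max() >= m):
                raise MeshError(f"element set {name!r} references nonexistent elements")

    def repair_orientation(self) -> int:
        """Swap two nodes of every negative-volume tet; return the repair count."""
        vol = self.signed_volumes()
        flipped = np.flatnonzero(vol < 0.0)
        if flipped.size:
            self.tets[flipped[:, None], [1, 2]] = self.tets[flipped[:, None], [2, 1]]
            logger.warning("repaired node ordering of %d inverted tets", flipped.size)
        return int(flipped.size)


@dataclass
class SurfacePatch:
    """Boundary faces of a tet mesh.

    ``faces`` are node-index triples oriented so ``normals`` (unit length)
    point away from the owning tet's centroid; ``owners`` maps each face to
    the single tet it belongs to.
    """

    faces: np.ndarray  # (k, 3) node ids
    normals: np.ndarray  # (k, 3) outward unit normals
    owners: np.ndarray  # (k,) element ids

    def face_centroids(self, mesh: TetMesh) -> np.ndarray:
        return mesh.nodes[self.faces].mean(axis=1)


def extract_surface(mesh: TetMesh) -> SurfacePatch:
    """Boundary faces = faces occurring in exactly one tet."""
    m = mesh.n_elements
    faces = mesh.tets[:, _TET_FACES].reshape(m * 4, 3)
    owners = np.repeat(np.arange(m), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    faces, owners = faces[boundary], owners[boundary]

    p = mesh.nodes[faces]
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # orient away from the owning tet centroid
    out = np.einsum("ij,ij->i", normals, p.mean(axis=1) - mesh.element_centroids()[owners])
    normals[out < 0] *= -1.0
    return SurfacePatch(faces=faces, normals=normals, owners=owners)


# ---------------------------------------------------------------------------
# Abaqus-INP subset
# ---------------------------------------------------------------------------

def _parse_keyword(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line.lstrip("*").split(",")]
    opts = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            opts[k.strip().upper()] = v.strip()
    return parts[0].upper(), opts


def read_inp(path: str | Path) -> TetMesh:
    """Read the *NODE / *ELEMENT(C3D4) / *NSET / *ELSET subset of Abaqus INP.

    Element blocks whose ELSET names a region label define element regions;
    other keywords are skipped with a warning.  1-based ids are remapped to
    contiguous 0-based indices.
    """
    path = Path(path)
    node_ids: list[int] = []
    coords: list[list[float]] = []
    elem_ids: list[int] = []
    conn: list[list[int]] = []
    elem_region: list[str] = []
    nsets: dict[str, list[int]] = {}
    elsets: dict[str, list[int]] = {}

    section = None
    section_opts: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw, opts = _parse_keyword(line)
                if kw == "NODE":
                    section = "node"
                elif kw == "ELEMENT":
                    etype = opts.get("TYPE", "")
                    if etype.upper() != "C3D4":
                        raise MeshError(f"{path}:{lineno}: unsupported element TYPE={etype!r}; only C3D4")
                    section = "element"
                elif kw == "NSET":
                    section = "nset"
                elif kw == "ELSET":
                    section = "elset"
                else:
                    logger.warning("%s:%d: skipping unknown keyword *%s", path.name, lineno, kw)
                    section = None
                section_opts = opts
                continue
            toks = [t for t in line.replace(",", " ").split() if t]
            try:
                if section == "node":
                    node_ids.append(int(toks[0]))
                    coords.append([float(t) for t in toks[1:4]])
                elif section == "element":
                    elem_ids.append(int(toks[0]))
                    conn.append([int(t) for t in toks[1:5]])
                    elem_region.append(section_opts.get("ELSET", "cortical").lower())
                elif section == "nset":
                    nsets.setdefault(section_opts["NSET"], []).extend(int(t) for t in toks)
                elif section == "elset":
                    elsets.setdefault(section_opts["ELSET"], []).extend(int(t) for t in toks)
            except (ValueError, IndexError) as exc:
                raise MeshError(f"{path}:{lineno}: malformed record {line!r}") from exc

    if len(set(elem_ids)) != len(elem_ids):
        seen, dup = set(), None
        for e in elem_ids:
            if e in seen:
                dup = e
                break
            seen.add(e)
        raise MeshError(f"{path}: duplicate element id {dup}")

    # remap in ascending-id order so writer's region-grouped blocks round-trip
    node_order = sorted(range(len(node_ids)), key=lambda i: node_ids[i])
    node_ids = [node_ids[i] for i in node_order]
    coords = [coords[i] for i in node_order]
    elem_order = sorted(range(len(elem_ids)), key=lambda i: elem_ids[i])
    elem_ids = [elem_ids[i] for i in elem_order]
    conn = [conn[i] for i in elem_order]
    elem_region = [elem_region[i] for i in elem_order]

    node_map = {nid: i for i, nid in enumerate(node_ids)}
    tets = np.empty((len(conn), 4), dtype=np.int64)
    for e, (eid, c) in enumerate(zip(elem_ids, conn)):
        for j, nid in enumerate(c):
            if nid not in node_map:
                raise MeshError(f"{path}: element {eid} references nonexistent node id {nid}")
            tets[e, j] = node_map[nid]

    elem_map = {eid: i for i, eid in enumerate(elem_ids)}
    mesh = TetMesh(
        nodes=np.asarray(coords, dtype=float),
        tets=tets,
        region=np.asarray(elem_region, dtype="U16"),
        node_sets={k: np.array(sorted(node_map[i] for i in v), dtype=np.int64) for k, v in nsets.items()},
        element_sets={k: np.array(sorted(elem_map[i] for i in v), dtype=np.int64) for k, v in elsets.items()},
    )
    vol = mesh.signed_volumes()
    if mesh.n_elements and vol.min() <= 0.0:
        zero = np.flatnonzero(vol == 0.0)
        if zero.size:
            raise MeshError(f"{path}: element {elem_ids[zero[0]]} is degenerate (zero volume)")
        mesh.repair_orientation()
    mesh.validate()
    return mesh


def write_inp(mesh: TetMesh, path: str | Path) -> None:
    """Write the INP subset; ids are restored to 1-based."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, 1):
            fh.write(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}\n")
        for label in np.unique(mesh.region):
            ids = np.flatnonzero(mesh.region == label)
            fh.write(f"*ELEMENT, TYPE=C3D4, ELSET={label}\n")
            for e in ids:
                n = mesh.tets[e] + 1
                fh.write(f"{e + 1}, {n[0]}, {n[1]}, {n[2]}, {n[3]}\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, ids + 1)
        for name, ids in mesh.element_sets.items():
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, ids + 1)


def _write_id_lines(fh, ids, per_line: int = 12) -> None:
    ids = np.asarray(ids)
    for i in range(0, ids.size, per_line):
        fh.write(", ".join(str(v) for v in ids[i : i + per_line]) + "\n")


# ---------------------------------------------------------------------------
# Native JSON
# ---------------------------------------------------------------------------

def write_json(mesh: TetMesh, path: str | Path) -> None:
    payload = {
        "format": "jawstrain-mesh",
        "version": 1,
        "nodes": mesh.nodes.tolist(),
        "tets": mesh.tets.tolist(),
        "region": mesh.region.tolist(),
        "node_sets": {k: v.tolist() for k, v in mesh.node_sets.items()},
        "element_sets": {k: v.tolist() for k, v in mesh.element_sets.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_json(path: str | Path) -> TetMesh:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "jawstrain-mesh":
        raise MeshError(f"{path}: not a jawstrain mesh JSON file")
    mesh = TetMesh(
        nodes=np.asarray(payload["nodes"], dtype=float),
        tets=np.asarray(payload["tets"], dtype=np.int64),
        region=np.asarray(payload["region"], dtype="U16"),
        node_sets={k: np.asarray(v, dtype=np.int64) for k, v in payload["node_sets"].items()},
        element_sets={k: np.asarray(v, dtype=np.int64) for k, v in payload["element_sets"].items()},
    )
    mesh.validate()
    return mesh


def read_mesh(path: str | Path, format: str | None = None) -> TetMesh:
    """Dispatch on ``format`` ('inp-subset' | 'native-json') or the file suffix."""
    path = Path(path)
    if format is None:
        format = "native-json" if path.suffix == ".json" else "inp-subset"
    if format == "inp-subset":
        return read_inp(path)
    if format == "native-json":
        return read_json(path)
    raise ValueError(f"unknown mesh format {format!r}")


def write_mesh(mesh: TetMesh, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "native-json" if path.suffix == ".json" else "inp-subset"
    if format == "inp-subset":
        write_inp(mesh, path)
    elif format == "native-json":
        write_json(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {format!r}")


# ---------------------------------------------------------------------------
# Legacy VTK unstructured grid
# ---------------------------------------------------------------------------

def write_vtk(mesh: TetMesh, fields: dict[str, np.ndarray] | None, path: str | Path) -> None:
    """Write an ASCII legacy-VTK unstructured grid with per-element scalar fields."""
    fields = fields or {}
    m = mesh.n_elements
    for name, values in fields.items():
        if np.asarray(values).shape != (m,):
            raise ValueError(f"field {name!r} has {np.asarray(values).size} values, mesh has {m} elements")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\njawstrain tet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        fh.write(f"CELLS {m} {5 * m}\n")
        for tet in mesh.tets:
            fh.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + ("\n" if m else ""))
        if fields:
            fh.write(f"CELL_DATA {m}\n")
            for name, values in fields.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(values, dtype=float):
                    fh.write(f"{float(v)!r}\n")


def read_vtk(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Minimal legacy-VTK reader (tetra cells only) for round-trip verification.

    Returns (points, tets, cell_fields).
    """
    tokens = Path(path).read_text().split()
    pos = tokens.index("POINTS")
    n = int(tokens[pos + 1])
    points = np.array(tokens[pos + 3 : pos + 3 + 3 * n], dtype=float).reshape(n, 3)
    pos = tokens.index("CELLS")
    m = int(tokens[pos + 1])
    raw = np.array(tokens[pos + 3 : pos + 3 + 5 * m], dtype=np.int64).reshape(m, 5)
    if not (raw[:, 0] == 4).all():
        raise MeshError(f"{path}: non-tetra cell found")
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        if tokens[i] == "SCALARS":
            name = tokens[i + 1]
            start = i + 6  # SCALARS name type 1 LOOKUP_TABLE default
            fields[name] = np.array(tokens[start : start + m], dtype=float)
            i = start + m
        else:
            i += 1
    return points, raw[:, 1:], fields
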