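"""Branching-cylinder phantom meshes and STL export.

A phantom spec is turned into three right circular cylinders — one per
branch — meeting at the carina, each a closed, watertight, outward-oriented
triangle surface. No CSG union is performed: the components overlap at the
junction and print slicers resolve the union (``overlapping`` mode).
``hollow`` mode emits, per branch, an inner shell at the lumen diameter
plus an outer shell offset outward by a wall thickness, for phantoms with
an open lumen.

Coordinates are centimetres by default; ``write_stl(..., unit="mm")``
scales by 10 for printers that assume millimetres.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import BRANCHES, DEFAULT_Y_SIGNS, BranchPolar, branch_endpoint
from .pipeline import TracheaModelSpec

__all__ = [
    "TriangleMesh",
    "build_branch_cylinder",
    "build_model_mesh",
    "write_stl",
    "read_stl",
    "mesh_summary",
]


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle surface: ``vertices`` (n, 3) float cm, ``triangles``
    (m, 3) int with counter-clockwise outward winding. ``components`` holds
    (vertex range, triangle range) pairs for meshes built from several
    closed parts."""

    vertices: np.ndarray
    triangles: np.ndarray
    components: tuple[tuple[tuple[int, int], tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=int)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle index out of range")

    def triangle_vertices(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.triangles]

    def areas(self) -> np.ndarray:
        tv = self.triangle_vertices()
        return 0.5 * np.linalg.norm(
            np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1
        )

    def signed_volume(self) -> float:
        """Sum of signed tetrahedron volumes; positive for a closed surface
        with outward-oriented (CCW) triangles."""
        tv = self.triangle_vertices()
        return float(
            np.einsum("ij,ij->i", tv[:, 0], np.cross(tv[:, 1], tv[:, 2])).sum() / 6.0
        )

    def is_watertight(self) -> bool:
        """True when every directed edge occurs exactly once and its
        reverse exactly once (closed, consistently oriented 2-manifold)."""
        edges: dict[tuple[int, int], int] = {}
        for a, b, c in self.triangles:
            for e in ((a, b), (b, c), (c, a)):
                if e[0] == e[1]:
                    return False
                edges[e] = edges.get(e, 0) + 1
        if any(cnt != 1 for cnt in edges.values()):
            return False
        return all((b, a) in edges for (a, b) in edges)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def split_components(self) -> list["TriangleMesh"]:
        if not self.components:
            return [self]
        out = []
        for (v0, v1), (t0, t1) in self.components:
            out.append(
                TriangleMesh(
                    vertices=self.vertices[v0:v1],
                    triangles=self.triangles[t0:t1] - v0,
                )
            )
        return out


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed (u, v, axis) basis: u x v = axis."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, a)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def _cylinder(start: np.ndarray, end: np.ndarray, diameter: float, n_sides: int
              ) -> TriangleMesh:
    if n_sides < 3:
        raise ValueError("n_sides must be >= 3")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    axis = end - start
    length = float(np.linalg.norm(axis))
    if length == 0:
        raise ValueError("degenerate cylinder: start equals end")
    u, v = _orthonormal_basis(axis)
    radius = diameter / 2.0
    t = np.linspace(0.0, 2.0 * math.pi, n_sides, endpoint=False)
    ring = radius * (np.outer(np.cos(t), u) + np.outer(np.sin(t), v))
    bottom = start + ring          # indices 0 .. n-1
    top = end + ring               # indices n .. 2n-1
    verts = np.vstack([bottom, top])

    n = n_sides
    tris = []
    for i in range(n):
        j = (i + 1) % n
        # side quad, outward (radial) winding
        tris.append((i, j, n + i))
        tris.append((n + i, j, n + j))
    for i in range(1, n - 1):
        tris.append((0, i + 1, i))                  # bottom cap, normal -axis
        tris.append((n, n + i, n + i + 1))          # top cap, normal +axis
    return TriangleMesh(vertices=verts, triangles=np.array(tris, dtype=int))


def build_branch_cylinder(
    branch: BranchPolar,
    diameter: float,
    y_sign: float = 1.0,
    n_sides: int = 64,
) -> TriangleMesh:
    """Closed right circular cylinder for one branch: axis from the carina
    (origin) to the branch endpoint, length r, the given lumen diameter,
    flat caps. Triangle count is ``4*n_sides - 4``."""
    end = np.array(branch_endpoint(branch, y_sign))
    return _cylinder(np.zeros(3), end, diameter, n_sides)


def _merge(meshes: Sequence[TriangleMesh]) -> TriangleMesh:
    verts, tris, comps = [], [], []
    v_off = t_off = 0
    for m in meshes:
        verts.append(m.vertices)
        tris.append(m.triangles + v_off)
        comps.append(((v_off, v_off + len(m.vertices)),
                      (t_off, t_off + len(m.triangles))))
        v_off += len(m.vertices)
        t_off += len(m.triangles)
    return TriangleMesh(
        vertices=np.vstack(verts),
        triangles=np.vstack(tris),
        components=tuple(comps),
    )


def build_model_mesh(
    spec: TracheaModelSpec,
    n_sides: int = 64,
    mode: str = "overlapping",
    wall_cm: float = 0.2,
) -> TriangleMesh:
    """Assemble the full phantom from a model spec.

    ``overlapping`` emits one closed cylinder per branch (three
    components); ``hollow`` emits per branch an inner shell at the lumen
    diameter and an outer shell at diameter + 2*wall (six components). Both
    modes keep every component watertight and outward-oriented; the
    overlap at the carina is left to the print slicer.
    """
    params = spec.polar()
    diams = spec.diameters()
    parts = []
    for b in BRANCHES:
        bp = params.branch(b)
        d = diams.branch(b)
        sign = DEFAULT_Y_SIGNS[b]
        if mode == "overlapping":
            parts.append(build_branch_cylinder(bp, d, sign, n_sides))
        elif mode == "hollow":
            if wall_cm <= 0:
                raise ValueError("wall_cm must be positive in hollow mode")
            if wall_cm >= d / 2.0:
                raise ValueError(
                    f"wall thickness {wall_cm} cm >= lumen radius {d / 2.0} cm "
                    f"for branch {b!r}"
                )
            parts.append(build_branch_cylinder(bp, d, sign, n_sides))
            parts.append(build_branch_cylinder(bp, d + 2.0 * wall_cm, sign, n_sides))
        else:
            raise ValueError(f"mode must be 'overlapping' or 'hollow', got {mode!r}")
    return _merge(parts)


# ---------------------------------------------------------------------------
# STL I/O
#
# Binary layout: 80-byte header, uint32 triangle count, then per triangle
# 12 float32 (normal + three vertices) + uint16 attribute = 50 bytes,
# little-endian. ASCII follows the solid/facet grammar.


def _facet_normals(mesh: TriangleMesh) -> np.ndarray:
    tv = mesh.triangle_vertices()
    n = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms == 0):
        raise ValueError("mesh contains a degenerate (zero-area) triangle")
    return n / norms[:, None]


def write_stl(mesh: TriangleMesh, path, format: str = "binary", unit: str = "cm") -> Path:
    """Write the mesh as STL. ``unit='mm'`` scales coordinates by 10 for
    printers assuming millimetres; the unit is noted in the header/solid
    name."""
    if unit not in ("cm", "mm"):
        raise ValueError("unit must be 'cm' or 'mm'")
    scale = 10.0 if unit == "mm" else 1.0
    path = Path(path)
    tv = mesh.triangle_vertices() * scale
    normals = _facet_normals(mesh)
    if format == "binary":
        header = f"tracheamorph phantom; units={unit} (scale x{scale:g} from cm)".encode()
        header = header[:80].ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tv)))
            for nrm, tri in zip(normals, tv):
                fh.write(struct.pack("<12fH", *nrm, *tri.ravel(), 0))
    elif format == "ascii":
        with open(path, "w") as fh:
            name = f"tracheamorph_{unit}"
            fh.write(f"solid {name}\n")
            for nrm, tri in zip(normals, tv):
                fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
                fh.write("    outer loop\n")
                for vtx in tri:
                    fh.write(f"      vertex {vtx[0]:.9e} {vtx[1]:.9e} {vtx[2]:.9e}\n")
                fh.write("    endloop\n")
                fh.write("  endfacet\n")
            fh.write(f"endsolid {name}\n")
    else:
        raise ValueError(f"format must be 'binary' or 'ascii', got {format!r}")
    return path


def read_stl(path) -> TriangleMesh:
    """Read an STL file (either flavour) back as a triangle soup: three
    vertices per triangle, no welding."""
    path = Path(path)
    raw = path.read_bytes()
    is_ascii = raw.lstrip()[:5] == b"solid" and b"facet" in raw[:2000]
    if is_ascii:
        tris = []
        current: list[list[float]] = []
        for line in raw.decode().splitlines():
            parts = line.split()
            if parts[:1] == ["vertex"]:
                current.append([float(x) for x in parts[1:4]])
                if len(current) == 3:
                    tris.append(current)
                    current = []
        soup = np.array(tris, dtype=float)
    else:
        (count,) = struct.unpack_from("<I", raw, 80)
        soup = np.empty((count, 3, 3), dtype=float)
        off = 84
        for i in range(count):
            vals = struct.unpack_from("<12fH", raw, off)
            soup[i] = np.array(vals[3:12], dtype=float).reshape(3, 3)
            off += 50
    n = len(soup)
    return TriangleMesh(
        vertices=soup.reshape(-1, 3),
        triangles=np.arange(3 * n, dtype=int).reshape(n, 3),
    )


def measure_axis_length(mesh: TriangleMesh) -> float:
    """Metrology helper: axial length of a single closed cylinder measured
    off the mesh as the distance between its two cap-ring centroids."""
    # the two rings are the first and second halves of the vertex array
    n = len(mesh.vertices) // 2
    c0 = mesh.vertices[:n].mean(axis=0)
    c1 = mesh.vertices[n:].mean(axis=0)
    return float(np.linalg.norm(c1 - c0))


def mesh_summary(mesh: TriangleMesh) -> dict:
    """JSON-ready counts, bounding box and per-component volumes."""
    comps = mesh.split_components()
    lo, hi = mesh.bounding_box()
    return {
        "n_vertices": int(len(mesh.vertices)),
        "n_triangles": int(len(mesh.triangles)),
        "n_components": len(comps),
        "bbox_min_cm": [float(x) for x in lo],
        "bbox_max_cm": [float(x) for x in hi],
        "component_volumes_cm3": [round(c.signed_volume(), 9) for c in comps],
        "watertight": all(c.is_watertight() for c in comps),
    }
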