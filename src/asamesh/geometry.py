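"""Micropillar layouts, design arithmetic and domain triangulation.

The micropillar array is the geometric template of anchored self-assembly:
inner pillars guide the contracting cell/fibrin sheet into a mesh pattern
while the outermost ("boundary") pillars anchor it against global shrinkage.
This module builds pillar layouts, evaluates the design numbers a substrate
implies (interspace volume, seeded cell count, mesh-opening density) and
triangulates the tissue domain -- the substrate rectangle minus the pillar
disks -- for the finite-element solver.

All coordinates are reference-configuration micrometres with the origin at
the lower-left corner of the substrate bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull

from .errors import (
    ClassificationError,
    DimensionError,
    GeometryError,
    RefinementError,
    UnsupportedLatticeError,
)

UL_PER_UM3 = 1e-9  # 1 uL = 1e9 um^3

def _tri_areas(p: np.ndarray) -> np.ndarray:
    """Signed areas of triangles given as (m, 3, 2) vertex arrays."""
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

_LATTICE_KINDS = ("square", "pentagon", "hexagon", "octagon", "custom")


@dataclass(frozen=True)
class PillarLayout:
    """Rigid-pillar template: disk centers/radius/height plus substrate bounds.

    Parameters
    ----------
    centers : (n, 2) array
        Pillar centers in um.
    radius, height : float
        Common pillar radius and height in um.
    substrate_bounds : (x0, y0, x1, y1)
        Axis-aligned substrate rectangle in um.
    lattice_kind : str
        One of ``square``, ``pentagon``, ``hexagon``, ``octagon``, ``custom``.
    pitch : float or None
        Center-to-center distance for regular lattices (um).
    interval : float or None
        Recorded surface-to-surface gap for square lattices (um); for a
        square lattice ``pitch = 2 * radius + interval``.
    """

    centers: np.ndarray
    radius: float
    height: float
    substrate_bounds: tuple[float, float, float, float]
    lattice_kind: str = "custom"
    pitch: float | None = None
    interval: float | None = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.size == 0:
            centers = centers.reshape(0, 2)
        centers = np.atleast_2d(centers)
        object.__setattr__(self, "centers", centers)
        if self.radius <= 0 or self.height <= 0:
            raise GeometryError("pillar radius and height must be positive")
        if self.lattice_kind not in _LATTICE_KINDS:
            raise GeometryError(f"unknown lattice kind {self.lattice_kind!r}")
        x0, y0, x1, y1 = self.substrate_bounds
        if x1 <= x0 or y1 <= y0:
            raise GeometryError("substrate bounds are empty")
        r = self.radius
        if len(centers):
            tol = 1e-9 * max(x1 - x0, y1 - y0)
            inside = (
                (centers[:, 0] - r >= x0 - tol)
                & (centers[:, 0] + r <= x1 + tol)
                & (centers[:, 1] - r >= y0 - tol)
                & (centers[:, 1] + r <= y1 + tol)
            )
            if not inside.all():
                raise GeometryError(
                    f"pillar disk(s) {np.flatnonzero(~inside).tolist()} "
                    "extend outside the substrate bounds"
                )
        if len(centers) > 1:
            d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 2 * r * (1 - 1e-12):
                raise GeometryError("pillar disks overlap")
        if self.lattice_kind == "square" and self.pitch is not None and self.interval is not None:
            if not math.isclose(self.pitch, 2 * r + self.interval, rel_tol=1e-12):
                raise GeometryError("square lattice requires pitch = 2*radius + interval")

    @property
    def n_pillars(self) -> int:
        return len(self.centers)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def bounds_size(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.substrate_bounds
        return x1 - x0, y1 - y0


@dataclass
class TissueDomain:
    """Conforming triangulation of the tissue region between pillars.

    ``nodes`` are reference coordinates X (um); ``triangles`` index into
    them counter-clockwise.  ``pillar_nodes[k]`` lists the nodes lying
    exactly (to 1e-6 * radius) on circle k; ``outer_nodes`` those on the
    substrate rectangle.  ``boundary_edges`` maps a tag ("outer",
    "pillar_k" or "free") to (m, 2) arrays of edge node pairs.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    pillar_nodes: dict[int, np.ndarray]
    outer_nodes: np.ndarray
    boundary_edges: dict[str, np.ndarray]
    element_size: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return _tri_areas(p)

    def total_area(self) -> float:
        return float(self.signed_areas().sum())


def build_square_layout(
    n_x: int,
    n_y: int,
    pillar_diameter: float,
    interval: float,
    substrate_bounds: tuple[float, float, float, float] | None = None,
    height: float = 200.0,
) -> PillarLayout:
    """Build an n_x x n_y square lattice of pillars at pitch = diameter + interval.

    If ``substrate_bounds`` is given the grid must fit with a margin of at
    least ``interval / 2`` on every side (this fitting rule admits a 16 x 16
    grid of 400 um pillars at 200 um interval on a 1 x 1 cm substrate, and
    rejects 17 x 17).  If absent, the bounds default to the pillar-disk hull
    expanded by one full interval per side.
    """
    if n_x < 2 or n_y < 2:
        raise DimensionError("a square layout needs at least 2 x 2 pillars")
    if pillar_diameter <= 0 or interval <= 0:
        raise DimensionError("pillar diameter and interval must be positive")
    pitch = pillar_diameter + interval
    span_x = n_x * pillar_diameter + (n_x - 1) * interval
    span_y = n_y * pillar_diameter + (n_y - 1) * interval
    if substrate_bounds is None:
        margin = interval
        sx = span_x + 2 * margin
        sy = span_y + 2 * margin
        substrate_bounds = (0.0, 0.0, sx, sy)
    else:
        x0, y0, x1, y1 = substrate_bounds
        margin = interval / 2.0
        tol = 1e-9 * pitch
        for name, span, length in (("x", span_x, x1 - x0), ("y", span_y, y1 - y0)):
            if span + 2 * margin > length + tol:
                raise DimensionError(
                    f"grid span {span:g} um plus {margin:g} um margin per side "
                    f"exceeds substrate {name}-extent {length:g} um"
                )
    x0, y0, x1, y1 = substrate_bounds
    cx = 0.5 * (x0 + x1)
    cy = 0.5 * (y0 + y1)
    ix = np.arange(n_x) - (n_x - 1) / 2.0
    iy = np.arange(n_y) - (n_y - 1) / 2.0
    gx, gy = np.meshgrid(ix * pitch + cx, iy * pitch + cy, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return PillarLayout(
        centers=centers,
        radius=pillar_diameter / 2.0,
        height=height,
        substrate_bounds=substrate_bounds,
        lattice_kind="square",
        pitch=pitch,
        interval=interval,
    )


def classify_pillars(layout: PillarLayout) -> tuple[np.ndarray, np.ndarray]:
    """Split pillar indices into (boundary, inner) by convex-hull membership.

    A pillar is a boundary pillar when its center lies on the convex hull of
    all centers (within 1e-6 of the lattice pitch); the rest are inner
    pillars that only template the mesh geometry.
    """
    centers = layout.centers
    if len(centers) < 3:
        raise ClassificationError("pillar classification needs at least 3 pillars")
    scale = layout.pitch if layout.pitch else float(
        np.linalg.norm(centers.max(0) - centers.min(0))
    )
    tol = 1e-6 * scale
    hull = ConvexHull(centers)
    # distance of each center to the nearest hull facet (equations are
    # outward normals with offsets: n.x + b <= 0 inside)
    dist = centers @ hull.equations[:, :2].T + hull.equations[:, 2]
    on_hull = dist.max(axis=1) >= -tol
    boundary = np.flatnonzero(on_hull)
    inner = np.flatnonzero(~on_hull)
    return boundary, inner


def interspace_volume(layout: PillarLayout) -> float:
    """Volume (uL) of the space between pillars: (bounds area - disk area) * height."""
    x0, y0, x1, y1 = layout.substrate_bounds
    area = (x1 - x0) * (y1 - y0)
    holes = layout.n_pillars * math.pi * layout.radius**2
    if holes > area:
        raise GeometryError("pillar disks exceed the substrate area")
    return (area - holes) * layout.height * UL_PER_UM3


class SeededCount(NamedTuple):
    exact: float
    two_sig: float


def seeded_cell_count(volume_ul: float, concentration_per_ml: float) -> SeededCount:
    """Cells seeded into a given interspace volume at a given concentration.

    ``count = concentration [mL^-1] * volume [uL] * 1e-3``; returned both
    exactly and rounded to 2 significant figures (the precision at which
    such seeding numbers are quoted).
    """
    if volume_ul < 0 or concentration_per_ml < 0:
        raise GeometryError("volume and concentration must be non-negative")
    exact = concentration_per_ml * volume_ul * 1e-3
    if exact == 0:
        return SeededCount(0.0, 0.0)
    ndigits = 1 - int(math.floor(math.log10(abs(exact))))
    return SeededCount(exact, round(exact, ndigits))


_POLYGON_CELL_AREA = {
    # unit-cell area of a regular polygon lattice with side = pitch
    "square": lambda p: p * p,
    "pentagon": lambda p: 0.25 * math.sqrt(5 * (5 + 2 * math.sqrt(5))) * p * p,
    "hexagon": lambda p: 1.5 * math.sqrt(3.0) * p * p,
    "octagon": lambda p: 2.0 * (1 + math.sqrt(2.0)) * p * p,
}


def opening_density(layout: PillarLayout) -> float:
    """Mesh openings per mm^2: one opening per lattice unit cell.

    For the square lattice this is 1 / pitch^2 with pitch in mm.  For the
    polygonal lattices the unit cell is the regular polygon with side equal
    to the pitch (documented convention; only the square value is tied to
    printed data).
    """
    if layout.lattice_kind == "custom" or layout.pitch is None:
        raise UnsupportedLatticeError("opening density needs a regular lattice with a pitch")
    pitch_mm = layout.pitch / 1000.0
    return 1.0 / _POLYGON_CELL_AREA[layout.lattice_kind](pitch_mm)


# ---------------------------------------------------------------------------
# Triangulation: structured cross-split grid with circle snapping.
#
# Each grid cell is split into 4 triangles through its center node, which
# keeps the connectivity invariant under the layout's reflections and
# rotations (a property the solver's symmetry checks rely on).  Nodes within
# half a cell of a pillar circle are snapped radially onto the circle,
# coincident nodes are merged, and triangles whose centroid falls inside a
# pillar disk are dropped, leaving a conforming mesh whose hole boundaries
# are inscribed polygons of the pillar circles.
# ---------------------------------------------------------------------------


def triangulate_domain(layout: PillarLayout, element_size: float) -> TissueDomain:
    """Triangulate substrate_bounds minus the pillar disks.

    ``element_size`` is the target edge length (um) and must not exceed
    half the pillar radius so that the circles are resolved (chord sagitta
    stays below element_size / 10).
    """
    if element_size <= 0:
        raise RefinementError("element size must be positive")
    if layout.n_pillars and element_size > layout.radius / 2 * (1 + 1e-12):
        raise RefinementError(
            f"element size {element_size:g} um exceeds radius/2 = {layout.radius / 2:g} um"
        )
    x0, y0, x1, y1 = layout.substrate_bounds
    W, H = x1 - x0, y1 - y0
    nx = max(2, round(W / element_size))
    ny = max(2, round(H / element_size))
    dx, dy = W / nx, H / ny

    gx = x0 + dx * np.arange(nx + 1)
    gy = y0 + dy * np.arange(ny + 1)
    cxs, cys = np.meshgrid(gx, gy, indexing="ij")
    corners = np.column_stack([cxs.ravel(), cys.ravel()])
    mx = x0 + dx * (np.arange(nx) + 0.5)
    my = y0 + dy * (np.arange(ny) + 0.5)
    mxs, mys = np.meshgrid(mx, my, indexing="ij")
    centers = np.column_stack([mxs.ravel(), mys.ravel()])
    nodes = np.vstack([corners, centers])
    n_corner = len(corners)

    def cid(i, j):  # corner index
        return i * (ny + 1) + j

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    c00 = cid(ii, jj)
    c10 = cid(ii + 1, jj)
    c01 = cid(ii, jj + 1)
    c11 = cid(ii + 1, jj + 1)
    m = n_corner + ii * ny + jj
    tris = np.concatenate(
        [
            np.column_stack([c00, c10, m]),
            np.column_stack([c10, c11, m]),
            np.column_stack([c11, c01, m]),
            np.column_stack([c01, c00, m]),
        ]
    )

    # snap nodes near each pillar circle radially onto it
    band = 0.5 * max(dx, dy) * (1 + 1e-9)
    on_circle = np.full(len(nodes), -1, dtype=int)  # pillar index or -1
    for k, c in enumerate(layout.centers):
        vec = nodes - c
        dist = np.hypot(vec[:, 0], vec[:, 1])
        sel = np.abs(dist - layout.radius) < band
        safe = dist[sel] > 1e-12
        scale = np.where(safe, layout.radius / np.maximum(dist[sel], 1e-12), 1.0)
        nodes[sel] = c + vec[sel] * scale[:, None]
        on_circle[sel] = k

    # merge nodes that snapped onto (numerically) the same circle point
    key = np.round(nodes / (1e-6 * min(dx, dy))).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    remap = inverse
    nodes = nodes[first]
    on_circle = on_circle[first]
    tris = remap[tris]

    # drop degenerate triangles and those whose centroid fell inside a disk
    p = nodes[tris]
    areas = _tri_areas(p)
    keep = areas > 1e-9 * dx * dy
    cent = p.mean(axis=1)
    for c in layout.centers:
        keep &= np.hypot(cent[:, 0] - c[0], cent[:, 1] - c[1]) >= layout.radius
    tris = tris[keep]

    # compact node numbering
    used = np.unique(tris)
    new_id = np.full(len(nodes), -1, dtype=int)
    new_id[used] = np.arange(len(used))
    nodes = nodes[used]
    on_circle = on_circle[used]
    tris = new_id[tris]

    tol = 1e-9 * max(W, H)
    outer = (
        (np.abs(nodes[:, 0] - x0) < tol)
        | (np.abs(nodes[:, 0] - x1) < tol)
        | (np.abs(nodes[:, 1] - y0) < tol)
        | (np.abs(nodes[:, 1] - y1) < tol)
    )

    nodes = _smooth(nodes, tris, fixed=outer | (on_circle >= 0))

    pillar_nodes = {
        k: np.flatnonzero(on_circle == k) for k in range(layout.n_pillars)
    }
    boundary_edges = _tag_boundary_edges(nodes, tris, layout, outer, on_circle, tol)

    domain = TissueDomain(
        nodes=nodes,
        triangles=tris,
        pillar_nodes=pillar_nodes,
        outer_nodes=np.flatnonzero(outer),
        boundary_edges=boundary_edges,
        element_size=element_size,
    )
    if domain.signed_areas().min() <= 0:
        raise GeometryError("triangulation produced a non-positive element area")
    return domain


def _smooth(nodes: np.ndarray, tris: np.ndarray, fixed: np.ndarray, n_pass: int = 2) -> np.ndarray:
    """Laplacian smoothing of interior nodes with inversion safeguard."""
    n = len(nodes)
    i = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2], tris[:, 1], tris[:, 2], tris[:, 0]])
    j = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0], tris[:, 0], tris[:, 1], tris[:, 2]])
    for _ in range(n_pass):
        acc = np.zeros_like(nodes)
        cnt = np.zeros(n)
        np.add.at(acc, i, nodes[j])
        np.add.at(cnt, i, 1.0)
        new = nodes.copy()
        free = ~fixed & (cnt > 0)
        new[free] = acc[free] / cnt[free][:, None]
        p = new[tris]
        areas = _tri_areas(p)
        for _ in range(4):
            bad = areas <= 0
            if not bad.any():
                break
            revert = np.unique(tris[bad])
            new[revert] = nodes[revert]
            p = new[tris]
            areas = _tri_areas(p)
        if (areas <= 0).any():
            return nodes  # give up smoothing rather than invert
        nodes = new
    return nodes


def _tag_boundary_edges(nodes, tris, layout, outer, on_circle, tol):
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    tags: dict[str, list] = {}
    for a, b in bedges:
        if outer[a] and outer[b]:
            tag = "outer"
        elif on_circle[a] >= 0 and on_circle[a] == on_circle[b]:
            tag = f"pillar_{on_circle[a]}"
        else:
            tag = "free"
        tags.setdefault(tag, []).append((a, b))
    return {t: np.array(v, dtype=int) for t, v in tags.items()}
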