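"""Triangular meshing of circular phantoms.

The phantom domain is a disk, so a Delaunay triangulation of a structured
ring point layout conforms to the (polygonal) boundary exactly.  Inclusion
circles receive their own node rings so that every inclusion boundary is
resolved by element edges; elements are labelled by region afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import Delaunay

if TYPE_CHECKING:  # pragma: no cover
    from .phantoms import PhantomSpec


class GeometryError(ValueError):
    """Raised for impossible phantom geometry (overlaps, protrusions)."""


@dataclass
class Mesh:
    """P1 triangle mesh of a circular phantom.

    Attributes
    ----------
    nodes : (N, 2) float array, mm
    elements : (E, 3) int array
        CCW-oriented vertex triples.
    boundary_nodes : (B,) int array
        Rim nodes ordered counter-clockwise starting near angle 0.
    regions : (E,) int array
        0 = background, k >= 1 = inclusion k.
    radius : float
        Phantom radius, mm.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_nodes: np.ndarray
    regions: np.ndarray
    radius: float
    _areas: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_areas(self) -> np.ndarray:
        """Signed (positive) areas of all elements."""
        if self._areas is None:
            p = self.nodes[self.elements]
            v1 = p[:, 1] - p[:, 0]
            v2 = p[:, 2] - p[:, 0]
            self._areas = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
        return self._areas

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def save_txt(self, path) -> None:
        """Plain-text exchange format: node lines `x y`, element lines `i j k region`."""
        with open(path, "w") as fh:
            fh.write(f"# radius {self.radius:.17g}\n")
            fh.write(f"# nodes {self.n_nodes} elements {self.n_elements}\n")
            for x, y in self.nodes:
                fh.write(f"{x:.17g} {y:.17g}\n")
            for (i, j, k), r in zip(self.elements, self.regions):
                fh.write(f"{i} {j} {k} {r}\n")
            fh.write("# boundary " + " ".join(map(str, self.boundary_nodes)) + "\n")

    @classmethod
    def load_txt(cls, path) -> "Mesh":
        with open(path) as fh:
            header = fh.readline().split()
            radius = float(header[2])
            counts = fh.readline().split()
            n_nodes, n_elems = int(counts[2]), int(counts[4])
            nodes = np.array(
                [[float(v) for v in fh.readline().split()] for _ in range(n_nodes)]
            )
            elems = np.empty((n_elems, 3), dtype=np.int64)
            regions = np.empty(n_elems, dtype=np.int64)
            for e in range(n_elems):
                i, j, k, r = (int(v) for v in fh.readline().split())
                elems[e] = (i, j, k)
                regions[e] = r
            boundary = np.array([int(v) for v in fh.readline().split()[2:]], dtype=np.int64)
        return cls(nodes, elems, boundary, regions, radius)


def _ring(radius: float, n: int, phase: float = 0.0) -> np.ndarray:
    theta = phase + 2.0 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(theta), np.sin(theta)])


def build_mesh(
    spec: "PhantomSpec",
    target_edge_length: float | None = None,
    layout_m: int | None = None,
) -> Mesh:
    """Triangulate a circular phantom with optional circular inclusions.

    Parameters
    ----------
    spec : PhantomSpec
        Geometry (diameter, inclusion disks); optical properties are ignored
        here and attached at assembly time via the region labels.
    target_edge_length : float, optional
        Nominal element edge, mm.  Default ``diameter / 16``.
    layout_m : int, optional
        When given, the rim node count is a multiple of ``layout_m`` with a
        node exactly at every acquisition angle ``2 pi k / m``, and one node
        is placed exactly one transport length (of the background) inside
        each of those angles.  This keeps source/detector placement exact
        instead of snapped to the nearest mesh node.

    Raises
    ------
    GeometryError
        If inclusions overlap each other or touch the phantom boundary.
    """
    R = spec.diameter / 2.0
    if R <= 0:
        raise GeometryError("phantom diameter must be positive")
    h = target_edge_length if target_edge_length is not None else spec.diameter / 16.0

    incs = list(spec.inclusions)
    for a, inc in enumerate(incs):
        c = np.asarray(inc.center, dtype=float)
        if np.hypot(*c) + inc.radius >= R:
            raise GeometryError(
                f"inclusion {a} (center {c}, r={inc.radius}) touches the phantom boundary"
            )
        for b in range(a + 1, len(incs)):
            other = incs[b]
            gap = np.hypot(*(c - np.asarray(other.center))) - inc.radius - other.radius
            if gap <= 0:
                raise GeometryError(f"inclusions {a} and {b} overlap (gap {gap:.3g} mm)")

    # concentric rings for the background disk
    n_rings = max(4, int(round(R / h)))
    pts = [np.zeros((1, 2))]
    for j in range(1, n_rings):
        r_j = R * j / n_rings
        n_j = max(6, int(round(2.0 * np.pi * r_j / h)))
        if layout_m is not None:
            # multiples of m keep the point set mirror-symmetric about every
            # source axis, so homogeneous-disk rows stay symmetric
            n_j = layout_m * max(1, int(round(n_j / layout_m)))
        pts.append(_ring(r_j, n_j, phase=(j % 2) * np.pi / n_j))
    n_rim = max(6, int(round(2.0 * np.pi * R / h)))
    if layout_m is not None:
        n_rim = layout_m * max(1, int(round(n_rim / layout_m)))
    pts.append(_ring(R, n_rim))

    # exact source-depth points at the layout angles
    fixed = []
    if layout_m is not None:
        depth = 1.0 / spec.background.mu_s_prime
        r_src = max(R - depth, 0.25 * R)
        fixed.append(_ring(r_src, layout_m))

    # inclusion boundary rings (>= 12 edges each) plus light interior fill
    inc_rings = []
    for inc in incs:
        c = np.asarray(inc.center, dtype=float)
        n_i = max(12, int(np.ceil(2.0 * np.pi * inc.radius / min(h, inc.radius * 0.7))))
        ring = c + _ring(inc.radius, n_i)
        inc_rings.append(ring)
        interior = [c[None, :]]
        r_in = inc.radius - min(h, inc.radius) * 0.7
        while r_in > 0.3 * min(h, inc.radius):
            n_in = max(6, int(round(2.0 * np.pi * r_in / min(h, inc.radius * 0.7))))
            interior.append(c + _ring(r_in, n_in, phase=0.3))
            r_in -= min(h, inc.radius) * 0.7
        inc_rings.append(np.vstack(interior))

    base = np.vstack(pts)
    extra_groups = inc_rings + fixed
    if extra_groups:
        extra = np.vstack(extra_groups)
        # drop background nodes that crowd inclusion/source nodes (keep the rim)
        keep = np.ones(base.shape[0], dtype=bool)
        interior_idx = np.arange(base.shape[0] - n_rim)
        d2 = ((base[interior_idx, None, :] - extra[None, :, :]) ** 2).sum(-1)
        crowd = d2.min(axis=1) < (0.55 * h) ** 2
        keep[interior_idx[crowd]] = False
        points = np.vstack([base[keep], extra])
    else:
        points = base
    if fixed and inc_rings:
        # a source point may coincide with an inclusion-ring point; dedupe
        _, unique_idx = np.unique(np.round(points / (1e-6 * R)), axis=0, return_index=True)
        points = points[np.sort(unique_idx)]

    tri = Delaunay(points)
    elements = tri.simplices.astype(np.int64)

    # enforce CCW orientation
    p = points[elements]
    signed = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
    )
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    signed = np.abs(signed)
    good = signed > 1e-12 * R * R  # drop degenerate slivers from co-circular points
    elements = elements[good]

    # region labels: inclusion k iff centroid inside disk k and all vertices within r+tol
    cent = points[elements].mean(axis=1)
    regions = np.zeros(elements.shape[0], dtype=np.int64)
    tol = 1e-9 * R
    for k, inc in enumerate(incs, start=1):
        c = np.asarray(inc.center, dtype=float)
        inside_c = np.hypot(cent[:, 0] - c[0], cent[:, 1] - c[1]) < inc.radius
        vdist = np.hypot(
            points[elements][:, :, 0] - c[0], points[elements][:, :, 1] - c[1]
        )
        inside_v = (vdist <= inc.radius + 1e-7 * inc.radius + tol).all(axis=1)
        regions[inside_c & inside_v] = k

    # rim nodes, CCW from angle ~0
    r_node = np.hypot(points[:, 0], points[:, 1])
    rim = np.nonzero(np.abs(r_node - R) < 1e-9 * R + 1e-12)[0]
    ang = np.arctan2(points[rim, 1], points[rim, 0]) % (2.0 * np.pi)
    rim = rim[np.argsort(ang)]

    return Mesh(points, elements, rim, regions, R)
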