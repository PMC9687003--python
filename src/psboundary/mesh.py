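"""Polygonal cell meshes with persistent identities.

A tissue is represented as an ordered sequence of :class:`CellFrame` objects.
Cell polygons within a frame form a conforming mesh: neighbouring cells share
vertices exactly, so cell-cell interfaces can be recovered as maximal chains
of shared polygon edges.  Image coordinate convention: x increases anterior to
posterior (AP axis), y is the dorsoventral (DV) axis; interface angles are
measured against the AP (+x) axis in degrees in [0, 180).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CellFrame",
    "TissueTimeSeries",
    "Interface",
    "polygon_centroid",
    "interface_angle",
]


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon given as an (n, 2) vertex array."""
    poly = np.asarray(poly, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:  # degenerate: fall back to vertex mean
        return poly.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def interface_angle(p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle of the chord p1->p2 relative to the AP (+x) axis, degrees in [0, 180)."""
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    ang = np.degrees(np.arctan2(d[1], d[0])) % 180.0
    return float(ang)


@dataclass
class Interface:
    """A shared edge chain between two cells, collapsed to its chord."""

    cell_a: int
    cell_b: int
    p1: np.ndarray
    p2: np.ndarray
    n_segments: int = 1

    @property
    def theta(self) -> float:
        return interface_angle(self.p1, self.p2)


@dataclass
class CellFrame:
    """One time point of a tracked cell mesh."""

    index: int
    time_min: float
    cells: dict[int, np.ndarray]
    _centroids: dict[int, np.ndarray] | None = field(default=None, repr=False)

    def centroid(self, cell_id: int) -> np.ndarray:
        return self.centroids()[cell_id]

    def centroids(self) -> dict[int, np.ndarray]:
        if self._centroids is None:
            self._centroids = {cid: polygon_centroid(p) for cid, p in self.cells.items()}
        return self._centroids

    def interfaces(self) -> list[Interface]:
        """All cell-cell interfaces as chords of maximal shared-edge chains."""
        seg_owner: dict[tuple, list[int]] = defaultdict(list)
        for cid, poly in self.cells.items():
            n = len(poly)
            for i in range(n):
                v1 = (float(poly[i, 0]), float(poly[i, 1]))
                v2 = (float(poly[(i + 1) % n, 0]), float(poly[(i + 1) % n, 1]))
                key = (v1, v2) if v1 <= v2 else (v2, v1)
                seg_owner[key].append(cid)
        pair_segs: dict[tuple[int, int], list[tuple]] = defaultdict(list)
        for seg, owners in seg_owner.items():
            if len(owners) == 2:
                a, b = sorted(owners)
                pair_segs[(a, b)].append(seg)
        out = []
        for (a, b), segs in pair_segs.items():
            p1, p2 = _chain_endpoints(segs)
            out.append(Interface(a, b, np.array(p1), np.array(p2), n_segments=len(segs)))
        return out

    def adjacency(self) -> nx.Graph:
        """Cell adjacency graph; edges carry the Interface object."""
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for itf in self.interfaces():
            g.add_edge(itf.cell_a, itf.cell_b, interface=itf)
        return g

    def ap_neighbours(self) -> set[tuple[int, int]]:
        """Unordered cell pairs whose centroid displacement is predominantly AP."""
        cent = self.centroids()
        pairs = set()
        for itf in self.interfaces():
            d = cent[itf.cell_b] - cent[itf.cell_a]
            if abs(d[0]) > abs(d[1]):
                pairs.add((itf.cell_a, itf.cell_b))
        return pairs


@dataclass
class TissueTimeSeries:
    """Tracked mesh over time plus (for synthetic tissues) ground truth.

    ``cell_truth`` columns: cell_id, column, row, parasegment, ap_rank, parity,
    en_positive.  ``interface_truth`` columns: cell_a, cell_b, cls (one of
    "psb", "minus1", "plus1", "other"); the mesh topology is constant over
    time, so interface classes are frame-independent.
    """

    frames: list[CellFrame]
    cell_truth: pd.DataFrame | None = None
    interface_truth: pd.DataFrame | None = None
    config: object | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_min for f in self.frames])

    def frame_at(self, time_min: float) -> CellFrame:
        i = int(np.argmin(np.abs(self.times - time_min)))
        return self.frames[i]


def _chain_endpoints(segs: list[tuple]) -> tuple[tuple, tuple]:
    """Endpoints of the polyline formed by a set of shared segments.

    Degree-1 vertices are the chain ends; a closed loop (pathological) falls
    back to the two most distant vertices.
    """
    if len(segs) == 1:
        return segs[0]
    deg: dict[tuple, int] = defaultdict(int)
    for v1, v2 in segs:
        deg[v1] += 1
        deg[v2] += 1
    ends = [v for v, d in deg.items() if d == 1]
    if len(ends) == 2:
        return ends[0], ends[1]
    verts = list(deg)
    arr = np.array(verts)
    d2 = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return verts[i], verts[j]
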