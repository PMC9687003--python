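"""Transcription-dot detection, tracking, cell assignment and parity calls.

Nuclear reporter dots (MS2/MCP-style) are detected by intensity thresholding
a 2D projection, linked frame-to-frame into tracks, assigned to cells by
point-in-polygon tests, and used to classify expressing cells and the
even/odd parity of expression stripes (even-numbered parasegments carry the
brighter dots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree
from skimage import measure

from .mesh import CellFrame

log = logging.getLogger(__name__)

__all__ = [
    "Dot",
    "DotTrack",
    "StripeLabel",
    "detect_dots",
    "track_dots",
    "assign_dots_to_cells",
    "assign_tracks",
    "classify_expressing_cells",
    "classify_stripe_parity",
    "build_kymograph",
]


@dataclass
class Dot:
    frame: int
    x: float
    y: float
    intensity: float


@dataclass
class DotTrack:
    """One dot followed through time; at most one detection per frame."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)
    cell_ids: list[int | None] = field(default_factory=list)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_position(self) -> tuple[float, float]:
        return self.positions[-1]


@dataclass
class StripeLabel:
    stripe_index: int
    cell_ids: set[int]
    parity: str = "unknown"  # "even" | "odd" | "unknown"


def detect_dots(image: np.ndarray, threshold: float, min_area: int = 1) -> list[Dot]:
    """Detect dots as connected components of pixels >= threshold.

    Each component yields one Dot at its intensity-weighted centroid, with
    intensity equal to the component's maximum pixel value.  Components with
    fewer than ``min_area`` pixels are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D intensity field, got shape {img.shape}")
    if img.size == 0:
        return []
    labels = measure.label(img >= threshold, connectivity=2)
    dots = []
    for prop in measure.regionprops(labels, intensity_image=img):
        if prop.area < min_area:
            continue
        cy, cx = prop.centroid_weighted
        dots.append(Dot(frame=0, x=float(cx), y=float(cy),
                        intensity=float(prop.intensity_max)))
    return dots


def track_dots(dots_per_frame: dict[int, list[Dot]], max_displacement: float,
               max_gap: int = 0) -> list[DotTrack]:
    """Greedy nearest-neighbour linking of dots through time.

    For each frame, candidate links between open tracks (last seen within
    ``max_gap`` frames) and new dots are sorted by distance and consumed
    closest-first; links longer than ``max_displacement`` are forbidden.
    Unlinked dots start new tracks.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    tracks: list[DotTrack] = []
    open_tracks: list[DotTrack] = []
    for f in sorted(dots_per_frame):
        dots = dots_per_frame[f]
        open_tracks = [t for t in open_tracks if f - t.last_frame <= max_gap + 1]
        cands = []
        for ti, t in enumerate(open_tracks):
            px, py = t.last_position
            for di, d in enumerate(dots):
                dist = float(np.hypot(d.x - px, d.y - py))
                if dist <= max_displacement:
                    cands.append((dist, ti, di))
        cands.sort(key=lambda c: (c[0], c[1], c[2]))  # closest first; deterministic ties
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in cands:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            t = open_tracks[ti]
            d = dots[di]
            t.frames.append(f)
            t.positions.append((d.x, d.y))
            t.intensities.append(d.intensity)
        for di, d in enumerate(dots):
            if di in used_d:
                continue
            t = DotTrack(track_id=len(tracks), frames=[f], positions=[(d.x, d.y)],
                         intensities=[d.intensity])
            tracks.append(t)
            open_tracks.append(t)
    return tracks


def assign_dots_to_cells(dots: list[Dot] | pd.DataFrame, frame: CellFrame,
                         capture_radius: float = 5.0) -> list[int | None]:
    """Map each dot to the cell containing it.

    A dot inside exactly one polygon gets that cell.  A dot on a shared edge
    or outside every polygon but within ``capture_radius`` of one is assigned
    to the cell with the nearest centroid (ties broken by smaller cell_id);
    anything further is unassigned (None).
    """
    if isinstance(dots, pd.DataFrame):
        pts = dots[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.array([[d.x, d.y] for d in dots], dtype=float)
    if len(pts) == 0:
        return []
    ids = sorted(frame.cells)
    polys = [Polygon(frame.cells[cid]) for cid in ids]
    tree = STRtree(polys)
    cent = frame.centroids()
    out: list[int | None] = []
    for x, y in pts:
        p = Point(x, y)
        hits = [int(i) for i in tree.query(p, predicate="intersects")]
        if len(hits) == 1:
            out.append(ids[hits[0]])
            continue
        if not hits:
            hits = [int(i) for i in tree.query(p.buffer(capture_radius),
                                               predicate="intersects")]
            hits = [i for i in hits if polys[i].distance(p) <= capture_radius]
        if not hits:
            out.append(None)
            continue
        # boundary tie or capture-radius rescue: nearest centroid, then smaller id
        best = min(hits, key=lambda i: (float(np.hypot(*(cent[ids[i]] - [x, y]))), ids[i]))
        out.append(ids[best])
    return out


def assign_tracks(tracks: list[DotTrack], frames: dict[int, CellFrame],
                  capture_radius: float = 5.0) -> list[DotTrack]:
    """Fill each track's per-frame cell assignment via point-in-polygon tests."""
    by_frame: dict[int, list[tuple[DotTrack, int]]] = {}
    for t in tracks:
        t.cell_ids = [None] * len(t.frames)
        for i, f in enumerate(t.frames):
            by_frame.setdefault(f, []).append((t, i))
    for f, entries in by_frame.items():
        if f not in frames:
            continue
        pts = [Dot(frame=f, x=t.positions[i][0], y=t.positions[i][1],
                   intensity=t.intensities[i]) for t, i in entries]
        assigned = assign_dots_to_cells(pts, frames[f], capture_radius)
        for (t, i), cid in zip(entries, assigned):
            t.cell_ids[i] = cid
    return tracks


def classify_expressing_cells(tracks: list[DotTrack], min_frames: int = 3,
                              window: tuple[int, int] | None = None) -> set[int]:
    """Cells with assigned dots in at least ``min_frames`` frames of the window."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if window is not None and window[1] < window[0]:
        raise ValueError("empty frame window")
    counts: dict[int, set[int]] = {}
    for t in tracks:
        for f, cid in zip(t.frames, t.cell_ids or [None] * len(t.frames)):
            if cid is None:
                continue
            if window is not None and not (window[0] <= f <= window[1]):
                continue
            counts.setdefault(cid, set()).add(f)
    return {cid for cid, frames in counts.items() if len(frames) >= min_frames}


def classify_stripe_parity(stripes: list[StripeLabel],
                           stripe_intensity: dict[int, float],
                           ratio_threshold: float = 1.5,
                           forced_parity: str | None = None) -> list[StripeLabel]:
    """Assign even/odd parity from alternating dot brightness along AP.

    If consecutive stripes alternate in mean dot intensity with a bright/dim
    ratio >= ``ratio_threshold``, the brighter class is called even (even
    parasegments carry the brighter reporter dots).  A single intensity class
    (e.g. after knockdown of the even-stripe activator) leaves parity unknown
    unless ``forced_parity`` is given; ambiguous alternation also yields
    unknown.
    """
    if not stripes:
        raise ValueError("need at least one stripe")
    if ratio_threshold < 1.0:
        raise ValueError("ratio_threshold must be >= 1")
    means = np.array([stripe_intensity[s.stripe_index] for s in stripes], dtype=float)
    if forced_parity is not None:
        for s in stripes:
            s.parity = forced_parity
        return stripes
    if len(stripes) == 1 or means.max() < ratio_threshold * means.min():
        for s in stripes:
            s.parity = "unknown"
        return stripes
    # split into bright/dim classes at the midpoint of the log-range
    cut = np.sqrt(means.max() * means.min())
    bright = means >= cut
    alternates = all(bright[i] != bright[i + 1] for i in range(len(bright) - 1))
    ratio_ok = means[bright].min() >= ratio_threshold * means[~bright].max()
    if not (alternates and ratio_ok):
        for s in stripes:
            s.parity = "unknown"
        return stripes
    for s, b in zip(stripes, bright):
        s.parity = "even" if b else "odd"
    return stripes


def build_kymograph(dots: pd.DataFrame, ap_bins: int, mode: str = "count",
                    ap_range: tuple[float, float] | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram dot AP positions per frame: an (ap_bins, n_frames) array.

    ``mode`` is "count" or "intensity" (summed intensity per bin).  Returns
    (kymograph, bin_edges, frame_values); column f sums to the number of dots
    (or total intensity) in that frame.
    """
    if ap_bins < 1:
        raise ValueError("ap_bins must be >= 1")
    if mode not in ("count", "intensity"):
        raise ValueError("mode must be 'count' or 'intensity'")
    frames = np.sort(dots.frame.unique()) if len(dots) else np.array([], dtype=int)
    if ap_range is None:
        if len(dots) == 0:
            ap_range = (0.0, 1.0)
        else:
            ap_range = (float(dots.x.min()), float(dots.x.max()) + 1e-9)
    edges = np.linspace(ap_range[0], ap_range[1], ap_bins + 1)
    kymo = np.zeros((ap_bins, len(frames)))
    for j, f in enumerate(frames):
        sub = dots[dots.frame == f]
        w = sub.intensity.to_numpy() if mode == "intensity" else None
        kymo[:, j], _ = np.histogram(sub.x, bins=edges, weights=w)
    return kymo, edges, frames
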