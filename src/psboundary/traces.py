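"""Fixed-embryo interface quantification: straightness and enrichment ratio.

A traced interface is an ordered polyline of pixel coordinates with one
intensity per sampled point (the 2-px line width of the original tracing is a
property of the upstream tool).  Two quantities are computed:

* straightness index S = chord length / arc length of the trace, in (0, 1],
  with S = 1 for a perfectly straight boundary;
* Myosin enrichment ratio R = log10[(PSB signal - PSB background) /
  (control signal - control background)], where each trace's background is the
  mean of its dimmest 20% of pixels and the signal is the mean of the
  remaining pixels.

Pairs whose boundary cells are dividing (``division_flag``) are excluded from
batch analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "LineTrace",
    "StraightnessResult",
    "EnrichmentResult",
    "UndefinedRatioError",
    "straightness_index",
    "trace_background",
    "enrichment_ratio",
    "batch_quantify",
]


class UndefinedRatioError(ValueError):
    """Background-subtracted signal was non-positive; the log-ratio is undefined."""


@dataclass
class LineTrace:
    """Ordered pixel coordinates and intensities along a traced interface."""

    coords: np.ndarray  # (n, 2)
    intensity: np.ndarray  # (n,)
    role: str = "psb"  # "psb" | "plus1"
    division_flag: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.coords) != len(self.intensity):
            raise ValueError("coords and intensity lengths differ")
        if len(self.coords) < 2:
            raise ValueError("a trace needs at least 2 points")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.coords, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))


@dataclass
class StraightnessResult:
    straightness: float
    chord_length: float
    arc_length: float


@dataclass
class EnrichmentResult:
    log10_ratio: float
    psb_background: float
    control_background: float
    psb_signal: float
    control_signal: float
    n_retained_psb: int
    n_retained_control: int


def straightness_index(trace: LineTrace) -> StraightnessResult:
    """Chord-to-arc ratio of the trace; 1.0 means perfectly straight."""
    arc = trace.arc_length
    if arc <= 0:
        raise ValueError("trace has zero arc length")
    chord = trace.chord_length
    if chord == 0:
        log.warning("trace endpoints coincide; straightness reported as 0")
    return StraightnessResult(straightness=chord / arc, chord_length=chord, arc_length=arc)


def trace_background(trace: LineTrace, fraction: float = 0.20
                     ) -> tuple[float, np.ndarray]:
    """Background level: mean of the dimmest ``ceil(fraction * n)`` pixels.

    Returns (background, retained_mask); the masked-out pixels are the ones
    counted as background and removed from signal computation.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(trace.intensity)
    if n < 2:
        raise ValueError("trace too short for background estimation")
    k = math.ceil(fraction * n)
    order = np.argsort(trace.intensity, kind="stable")
    mask = np.ones(n, dtype=bool)
    mask[order[:k]] = False
    background = float(trace.intensity[order[:k]].mean())
    return background, mask


def enrichment_ratio(psb: LineTrace, control: LineTrace, fraction: float = 0.20
                     ) -> EnrichmentResult:
    """log10 ratio of background-subtracted PSB signal over control signal.

    Signal is the mean of the retained (non-background) pixels of each trace,
    each trace using its own background.  A non-positive background-subtracted
    signal on either side makes the ratio undefined and raises
    :class:`UndefinedRatioError` (the caller records the exclusion).
    """
    bg_p, mask_p = trace_background(psb, fraction)
    bg_c, mask_c = trace_background(control, fraction)
    sig_p = float(psb.intensity[mask_p].mean())
    sig_c = float(control.intensity[mask_c].mean())
    num, den = sig_p - bg_p, sig_c - bg_c
    if num <= 0 or den <= 0:
        raise UndefinedRatioError(
            f"non-positive background-subtracted signal (psb={num:.3g}, control={den:.3g})")
    return EnrichmentResult(
        log10_ratio=math.log10(num / den),
        psb_background=bg_p, control_background=bg_c,
        psb_signal=sig_p, control_signal=sig_c,
        n_retained_psb=int(mask_p.sum()), n_retained_control=int(mask_c.sum()),
    )


def batch_quantify(pairs: list[tuple[LineTrace, LineTrace, bool]],
                   fraction: float = 0.20) -> pd.DataFrame:
    """Per-pair straightness (PSB trace) and enrichment ratio, exclusions applied.

    Division-flagged pairs are dropped before computation; pairs with an
    undefined ratio are kept in the table with ``excluded=True`` and a reason.
    Returns columns: pair, straightness, log10_ratio, excluded, reason.
    """
    rows = []
    for i, (psb, control, flagged) in enumerate(pairs):
        if flagged:
            log.warning("pair %d excluded: boundary cells dividing", i)
            continue
        row = {"pair": i, "straightness": straightness_index(psb).straightness,
               "log10_ratio": np.nan, "excluded": False, "reason": ""}
        try:
            row["log10_ratio"] = enrichment_ratio(psb, control, fraction).log10_ratio
        except UndefinedRatioError as e:
            row["excluded"] = True
            row["reason"] = "undefined_ratio"
            log.warning("pair %d excluded: %s", i, e)
        rows.append(row)
    if not rows:
        log.warning("all trace pairs excluded; empty result")
    return pd.DataFrame(rows, columns=["pair", "straightness", "log10_ratio",
                                       "excluded", "reason"])


def summarize_for_boxplot(values: np.ndarray) -> dict:
    """Quartiles and 1.5*IQR whisker limits, as drawn in standard box plots."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return {"n": int(v.size), "q1": float(q1), "median": float(med), "q3": float(q3),
            "whisker_lo": float(inside.min()) if inside.size else float("nan"),
            "whisker_hi": float(inside.max()) if inside.size else float("nan"),
            "mean": float(v.mean())}
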