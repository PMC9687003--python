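"""Synthetic germband generator with known ground truth.

Generates the four kinds of input the analysis modules consume:

* a stripe-patterned honeycomb epithelium whose parasegmental-boundary (PSB)
  interfaces are tunably better aligned with the DV axis than control
  interfaces (``generate_epithelium``);
* nuclear transcription-dot tables/movies whose brightness alternates with
  parasegment parity (``generate_dot_movie``, ``render_dots``);
* interface line traces with a known Myosin-like enrichment factor and
  background fraction (``generate_line_trace_set``);
* gene-annotation tables for the in-silico screen with a planted three-way
  intersection (``generate_screen_fixture``).

Tissue geometry: pointy-top hexagonal cells in ``n_columns`` AP columns by
``n_rows`` DV rows.  The left/right (vertical) edges of each hexagon are the
AP interfaces between AP-neighbour cells; each mesh vertex belongs to exactly
one vertical edge, so rotating a vertical edge about its midpoint re-orients
that interface without breaking the conforming mesh.  Interface disorder is
therefore angular: edge rotation angles are wrapped-normal with standard
deviation sigma(t) = sigma0 + sigma1 * max(t, 0) degrees, and ground-truth
PSB edges use a (1 - beta)-scaled deviation.  Cell intercalation is emulated
by this growing angular-disorder schedule, not by topological T1 swaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, ScreenFixtureConfig, SynthesisConfig, TraceSetConfig
from .mesh import CellFrame, TissueTimeSeries
from .traces import LineTrace

__all__ = [
    "generate_epithelium",
    "generate_dot_movie",
    "render_dots",
    "generate_line_trace_set",
    "generate_screen_fixture",
    "ScreenFixture",
    "slot_class",
]

_S3 = math.sqrt(3.0) / 2.0


def slot_class(c: int, cfg: SynthesisConfig) -> str:
    """Ground-truth class of the vertical-edge column ``c`` (0..n_columns).

    Slot ``c`` separates cell columns ``c-1`` and ``c``.  Internal PSB slots
    sit at multiples of the parasegment width; the -1 and +1 control slots
    are one cell anterior / posterior of each internal PSB.
    """
    w = cfg.parasegment_width_cells
    if c <= 0 or c >= cfg.n_columns:
        return "border"
    psb = {p * w for p in range(1, cfg.n_parasegments)}
    plus1 = {b + 1 for b in psb}
    minus1 = {b - 1 for b in psb}
    if c in psb:
        return "psb"
    hit_p, hit_m = c in plus1, c in minus1
    if hit_p and hit_m:  # width-2 parasegments: +1 of one PSB is -1 of the next
        return "other"
    if hit_p:
        return "plus1"
    if hit_m:
        return "minus1"
    return "other"


def sigma_at(cls: str, t: float, cfg: SynthesisConfig) -> float:
    """Angular jitter sd (degrees) for an interface class at time t (min)."""
    base = cfg.sigma0 + cfg.sigma1 * max(t, 0.0)
    if t < 0 and cfg.initial_alignment:
        # mesoderm-pull emulation: all columns equally aligned before onset
        return cfg.sigma0
    if cls == "psb":
        relax = 0.0
        if cfg.initial_alignment and cfg.psb_relax_min > 0:
            relax = max(0.0, 1.0 - max(t, 0.0) / cfg.psb_relax_min)
        return (1.0 - cfg.beta) * base + cfg.beta * cfg.sigma0 * relax
    return base


def generate_epithelium(config: SynthesisConfig) -> TissueTimeSeries:
    """Generate a tracked stripe-patterned tissue with ground-truth labels."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.cell_radius
    nc, nr, w = cfg.n_columns, cfg.n_rows, cfg.parasegment_width_cells

    # per-slot-column class and rest x positions; slot rows span -1..n_rows
    cls_by_c = np.array([slot_class(c, cfg) for c in range(nc + 1)])
    rr = np.arange(-1, nr + 1)  # slot rows
    cc = np.arange(nc + 1)
    ex = R * _S3 * (2 * cc[:, None] + (rr[None, :] % 2))  # (nc+1, nr+2)
    ey = 1.5 * R * rr[None, :] * np.ones_like(ex)

    # cell -> vertex-slot indexing, computed once (topology is constant)
    c_idx, r_idx = np.meshgrid(np.arange(nc), np.arange(nr), indexing="ij")
    off = r_idx % 2
    ri = r_idx + 1  # shift slot-row -1..nr to array index 0..nr+1

    def poly_index(top, bot):
        """Assemble (nc, nr, 6, 2) polygons from TOP/BOT vertex arrays."""
        pts = [
            top[c_idx + off, ri - 1],  # B: top vertex of the slot below
            bot[c_idx + 1, ri],        # RB
            top[c_idx + 1, ri],        # RT
            bot[c_idx + off, ri + 1],  # T: bottom vertex of the slot above
            top[c_idx, ri],            # LT
            bot[c_idx, ri],            # LB
        ]
        return np.stack(pts, axis=2)

    truth_rows = []
    for c in range(nc):
        for r in range(nr):
            ps = c // w
            truth_rows.append({
                "cell_id": r * nc + c, "column": c, "row": r,
                "parasegment": ps, "ap_rank": c % w,
                "parity": "even" if ps % 2 == 0 else "odd",
                "en_positive": (c % w) < cfg.en_stripe_width,
            })
    cell_truth = pd.DataFrame(truth_rows)

    itf_rows = []
    for c in range(1, nc):
        cls = slot_class(c, cfg)
        for r in range(nr):
            a, b = r * nc + (c - 1), r * nc + c
            itf_rows.append({"cell_a": a, "cell_b": b, "cls": cls})
    interface_truth = pd.DataFrame(itf_rows)

    frames = []
    for k, t in enumerate(cfg.frame_times):
        sig = np.array([sigma_at(cls, t, cfg) for cls in cls_by_c])  # per slot column
        sig2d = np.broadcast_to(sig[:, None], ex.shape)
        phi = rng.standard_normal(ex.shape) * sig2d
        phi = (phi + 90.0) % 180.0 - 90.0  # undirected edge: wrap into (-90, 90]
        L = R / (1.0 + np.abs(phi) / 90.0)  # edges shorten as they rotate (T1 approach)
        ux = np.sin(np.radians(phi)) * L / 2.0
        uy = np.cos(np.radians(phi)) * L / 2.0
        jsd = cfg.vertex_jitter_frac * R * sig2d / 90.0
        jit = rng.standard_normal(ex.shape + (4,)) * jsd[..., None]
        top = np.stack([ex + ux + jit[..., 0], ey + uy + jit[..., 1]], axis=-1)
        bot = np.stack([ex - ux + jit[..., 2], ey - uy + jit[..., 3]], axis=-1)
        polys = poly_index(top, bot)  # (nc, nr, 6, 2)
        cells = {r * nc + c: polys[c, r] for c in range(nc) for r in range(nr)}
        frames.append(CellFrame(index=k, time_min=t, cells=cells))

    return TissueTimeSeries(frames=frames, cell_truth=cell_truth,
                            interface_truth=interface_truth, config=cfg)


def generate_dot_movie(tissue: TissueTimeSeries, config: SynthesisConfig | None = None,
                       ) -> pd.DataFrame:
    """Emit per-frame transcription dots for en-positive cells.

    Each en-positive cell produces one dot per frame with probability ``p_on``
    at its centroid plus isotropic Gaussian jitter; dot intensity is
    ``dot_base_intensity`` times ``parity_brightness_ratio`` in even-numbered
    parasegments, plus additive Gaussian noise (clipped at zero).  Returns a
    table (frame, time_min, dot_id, x, y, intensity, truth_cell_id).
    """
    cfg = (config or tissue.config)
    if cfg is None:
        raise ConfigError("no SynthesisConfig available for the dot model")
    cfg = cfg.validate()
    if tissue.cell_truth is None:
        raise ConfigError("tissue carries no ground truth (en_positive / parity)")
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from the mesh
    en = tissue.cell_truth[tissue.cell_truth.en_positive]
    bright = {row.cell_id: cfg.parity_brightness_ratio if row.parity == "even" else 1.0
              for row in en.itertuples()}
    rows = []
    dot_id = 0
    for frame in tissue.frames:
        cent = frame.centroids()
        for cid in en.cell_id:
            if rng.random() > cfg.p_on:
                continue
            pos = cent[cid] + rng.normal(0.0, cfg.dot_jitter, 2)
            inten = cfg.dot_base_intensity * bright[cid] + rng.normal(0.0, cfg.dot_noise_sd)
            rows.append({"frame": frame.index, "time_min": frame.time_min,
                         "dot_id": dot_id, "x": pos[0], "y": pos[1],
                         "intensity": max(inten, 0.0), "truth_cell_id": cid})
            dot_id += 1
    cols = ["frame", "time_min", "dot_id", "x", "y", "intensity", "truth_cell_id"]
    return pd.DataFrame(rows, columns=cols)


def render_dots(dots: pd.DataFrame, shape: tuple[int, int], psf_sigma: float = 1.5,
                frame: int | None = None) -> np.ndarray:
    """Paint dots as isotropic Gaussian spots into an image (or stack).

    ``shape`` is (height, width) in pixels; dot (x, y) map to (col, row).
    Returns a 2D array for a single frame, else a (n_frames, h, w) stack over
    the frames present in the table.
    """
    if frame is not None:
        sub = dots[dots.frame == frame]
        return _paint(sub, shape, psf_sigma)
    frames = sorted(dots.frame.unique())
    return np.stack([_paint(dots[dots.frame == f], shape, psf_sigma) for f in frames])


def _paint(sub: pd.DataFrame, shape: tuple[int, int], psf_sigma: float) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for row in sub.itertuples():
        r2 = (xx - row.x) ** 2 + (yy - row.y) ** 2
        img += row.intensity * np.exp(-r2 / (2.0 * psf_sigma**2))
    return img


def generate_line_trace_set(config: TraceSetConfig) -> list[tuple[LineTrace, LineTrace, bool]]:
    """Generate (PSB, +1 control) trace pairs with a known enrichment factor.

    Each trace has ``ceil(background_fraction * trace_length)`` pixels at the
    background level and the rest at the signal level (times the enrichment
    factor for the PSB trace), plus Gaussian noise; the positions of the
    background pixels along the trace are randomized.  Trace coordinates are a
    DV-running polyline with optional lateral wiggle so straightness can be
    exercised on the same objects.

    With the default zero background level the downstream enrichment ratio
    recovers log10(f) exactly; a nonzero background level B shifts the planted
    ratio to (f*S - B) / (S - B).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.trace_length
    n_bg = math.ceil(cfg.background_fraction * n)
    out = []
    for i in range(cfg.n_pairs):
        pair = []
        for role, factor in (("psb", cfg.enrichment_factor), ("plus1", 1.0)):
            inten = np.full(n, cfg.signal_level * factor)
            inten[:n_bg] = cfg.background_level
            rng.shuffle(inten)
            inten = inten + rng.normal(0.0, cfg.noise_sd, n)
            x = rng.normal(0.0, cfg.wiggle_sd, n) if cfg.wiggle_sd > 0 else np.zeros(n)
            coords = np.column_stack([x, np.arange(n, dtype=float)])
            pair.append(LineTrace(coords=coords, intensity=inten, role=role,
                                  division_flag=False, meta={"pair": i}))
        flagged = bool(rng.random() < cfg.division_flag_prob)
        pair[0].division_flag = pair[1].division_flag = flagged
        out.append((pair[0], pair[1], flagged))
    return out


@dataclass
class ScreenFixture:
    """Criterion lists + annotation tables + planted ground truth."""

    striped_symbols: list[str]
    surface_symbols: list[str]
    pairrule_symbols: list[str]
    alias_table: pd.DataFrame  # columns: symbol, canonical_id
    temporal_table: pd.DataFrame  # canonical_id, expr_0_6h, expr_0_24h
    flags_table: pd.DataFrame  # canonical_id, not_striped_by_eye, non_surface_role
    truth: dict = field(default_factory=dict)


def generate_screen_fixture(config: ScreenFixtureConfig) -> ScreenFixture:
    """Build screen input tables with a planted three-way intersection.

    The Venn-region sizes in the config are exact by construction;
    ``truth["intersection"]`` and ``truth["post_qc"]`` hold the expected
    outputs of the screen module on these tables.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = [f"GENE{i:04d}" for i in range(n)]
    regions = (
        ("s", cfg.only_striped), ("u", cfg.only_surface), ("p", cfg.only_pairrule),
        ("su", cfg.striped_surface), ("sp", cfg.striped_pairrule),
        ("up", cfg.surface_pairrule), ("sup", cfg.all_three),
    )
    order = rng.permutation(n)
    striped, surface, pairrule = set(), set(), set()
    i = 0
    for tag, size in regions:
        block = [genes[j] for j in order[i:i + size]]
        i += size
        if "s" in tag:
            striped.update(block)
        if "u" in tag:
            surface.update(block)
        if "p" in tag:
            pairrule.update(block)
    intersection = striped & surface & pairrule

    # temporal expression: low-early genes get < 5% of 0-24 h expression in 0-6 h
    low_early = set(g for g in genes if rng.random() < cfg.frac_low_early)
    trows = []
    for g in genes:
        total = rng.uniform(50.0, 150.0)
        frac = rng.uniform(0.0, 0.045) if g in low_early else rng.uniform(0.06, 0.6)
        trows.append({"canonical_id": g, "expr_0_6h": frac * total, "expr_0_24h": total})
    temporal = pd.DataFrame(trows)

    frows = []
    for g in genes:
        frows.append({"canonical_id": g,
                      "not_striped_by_eye": bool(rng.random() < cfg.frac_not_striped_by_eye),
                      "non_surface_role": bool(rng.random() < cfg.frac_non_surface_role)})
    flags = pd.DataFrame(frows)

    # inject aliases into the criterion lists
    listed = sorted(striped | surface | pairrule)
    n_alias = min(cfg.n_aliases, len(listed))
    aliased = list(rng.choice(listed, size=n_alias, replace=False)) if n_alias else []
    alias_of = {g: f"alt-{g}" for g in aliased}
    alias_rows = [{"symbol": a, "canonical_id": g} for g, a in alias_of.items()]
    alias_table = pd.DataFrame(alias_rows, columns=["symbol", "canonical_id"])

    def symbolize(s: set[str]) -> list[str]:
        return sorted(alias_of.get(g, g) for g in s)

    flagged = {
        g: [r for r, hit in (
            ("not_striped_by_eye", bool(flags.set_index("canonical_id")
                                        .loc[g, "not_striped_by_eye"])),
            ("low_early_expression", g in low_early),
            ("non_surface_role", bool(flags.set_index("canonical_id")
                                      .loc[g, "non_surface_role"])),
        ) if hit]
        for g in intersection
    }
    post_qc = {g for g, rules in flagged.items() if not rules}

    truth = {
        "striped": striped, "surface": surface, "pairrule": pairrule,
        "intersection": intersection, "post_qc": post_qc,
        "exclusions": {g: r for g, r in flagged.items() if r},
        "low_early": low_early,
    }
    return ScreenFixture(
        striped_symbols=symbolize(striped), surface_symbols=symbolize(surface),
        pairrule_symbols=symbolize(pairrule), alias_table=alias_table,
        temporal_table=temporal, flags_table=flags, truth=truth,
    )
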