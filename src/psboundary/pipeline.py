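"""End-to-end pipeline: simulate -> track -> boundaries -> statistics.

Runs the enabled stages on a synthetic embryo and writes all artifacts
(CSV tables, plots, a log and the serialized effective config) into an
output directory.  Every output is re-derivable from the serialized config
alone; two runs with the same config produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import alignment, boundaries, dots as dotmod, io as pio, screen as screenmod
from .alignment import ks_report_table
from .config import PipelineConfig, dump_config
from .synthetic import (generate_dot_movie, generate_epithelium,
                        generate_line_trace_set, generate_screen_fixture)
from .traces import batch_quantify

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "track", "boundaries", "coalign", "fixedquant", "screen")

__all__ = ["run_pipeline", "ALL_STAGES"]


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Execute the enabled stages; returns the output directory.

    Stage dependencies (track needs simulate, etc.) are resolved by running
    upstream stages in memory even when their outputs are not requested.
    """
    cfg = config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("psboundary")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        dump_config(cfg, out / "config.yaml")
        need_tissue = any(s in stages for s in ("simulate", "track", "boundaries",
                                                "coalign"))
        tissue = dot_table = None
        if need_tissue:
            log.info("simulate: generating synthetic embryo (seed=%d)",
                     cfg.synthesis.seed)
            tissue = generate_epithelium(cfg.synthesis)
            dot_table = generate_dot_movie(tissue)
        if "simulate" in stages:
            pio.write_mesh_json(tissue, out / "mesh.json")
            pio.write_dots_csv(dot_table, out / "dots.csv")

        expressing = interface_table = None
        if any(s in stages for s in ("track", "boundaries", "coalign")):
            log.info("track: linking %d dots and assigning to cells", len(dot_table))
            per_frame = {
                f: [dotmod.Dot(frame=int(f), x=r.x, y=r.y, intensity=r.intensity)
                    for r in sub.itertuples()]
                for f, sub in dot_table.groupby("frame")
            }
            tracks = dotmod.track_dots(per_frame, cfg.max_displacement, cfg.max_gap)
            frames_by_idx = {f.index: f for f in tissue.frames}
            dotmod.assign_tracks(tracks, frames_by_idx, cfg.capture_radius)
            expressing = dotmod.classify_expressing_cells(
                tracks, min_frames=cfg.min_frames_expressing)
            if "track" in stages:
                rows = [{"track_id": t.track_id, "frame": f, "x": p[0], "y": p[1],
                         "intensity": i, "cell_id": c}
                        for t in tracks
                        for f, p, i, c in zip(t.frames, t.positions, t.intensities,
                                              t.cell_ids)]
                pd.DataFrame(rows, columns=["track_id", "frame", "x", "y",
                                            "intensity", "cell_id"]
                             ).to_csv(out / "tracks.csv", index=False)
                pd.DataFrame({"cell_id": sorted(expressing)}
                             ).to_csv(out / "expressing_cells.csv", index=False)
                kymo, edges, fr = dotmod.build_kymograph(dot_table, ap_bins=40)
                pd.DataFrame(kymo).to_csv(out / "kymograph.csv", index=False)
                if cfg.make_plots:
                    from .plots import plot_kymograph
                    plot_kymograph(kymo, edges, fr, out / "kymograph.png")

        if any(s in stages for s in ("boundaries", "coalign")):
            log.info("boundaries: classifying interfaces in %d frames",
                     len(tissue.frames))
            by_frame = {f.index: expressing for f in tissue.frames}
            interface_table = boundaries.interfaces_to_table(tissue, by_frame)
            if "boundaries" in stages:
                interface_table.to_csv(out / "interfaces.csv", index=False)

        if "coalign" in stages:
            log.info("coalign: curves and KS comparison at t = %g min", cfg.t_test_min)
            report = alignment.compare_conditions(
                interface_table, t_test=cfg.t_test_min,
                t_halfwidth=cfg.t_window_halfwidth, span=cfg.loess_span,
                threshold=cfg.coalign_threshold_deg, window=cfg.window)
            report["curves"].to_csv(out / "coalignment.csv", index=False)
            ks_report_table(report["ks"], cfg.t_test_min
                            ).to_csv(out / "ks_tests.csv", index=False)
            if cfg.make_plots:
                from .plots import plot_coalignment_curves
                plot_coalignment_curves(report["curves"], out / "coalignment.png",
                                        threshold=cfg.coalign_threshold_deg)

        if "fixedquant" in stages:
            log.info("fixedquant: %d synthetic trace pairs", cfg.traces.n_pairs)
            pairs = generate_line_trace_set(cfg.traces)
            pio.write_traces_csv(pairs, out / "traces.csv")
            results = batch_quantify(pairs, fraction=cfg.background_fraction)
            results.to_csv(out / "trace_results.csv", index=False)

        if "screen" in stages:
            log.info("screen: fixture with %d genes", cfg.screen.n_genes)
            fx = generate_screen_fixture(cfg.screen)
            res = screenmod.run_screen(
                fx.striped_symbols, fx.surface_symbols, fx.pairrule_symbols,
                fx.alias_table, fx.temporal_table, fx.flags_table,
                early_threshold=cfg.early_fraction_threshold)
            rows = [{"canonical_id": g,
                     "in_post_qc": g in res.post_qc,
                     "exclusion_rules": ";".join(res.exclusions.get(g, []))}
                    for g in sorted(res.intersection)]
            pd.DataFrame(rows, columns=["canonical_id", "in_post_qc",
                                        "exclusion_rules"]
                         ).to_csv(out / "screen_report.csv", index=False)
            funnel = res.funnel()
            pd.DataFrame([funnel]).to_csv(out / "screen_funnel.csv", index=False)
        log.info("pipeline finished: %s", out)
    except Exception:
        log.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
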