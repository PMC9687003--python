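"""Configuration objects for the synthetic generator and the pipeline.

All defaults encode the study conditions the analyses assume: parasegments
~4 cells wide along AP, an analysis window of -10 to 50 min around extension
onset, a 60 deg co-alignment threshold, LOESS span 0.75, a 20% background
pixel fraction for line traces, and comparisons at t = 30 min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "SynthesisConfig",
    "TraceSetConfig",
    "ScreenFixtureConfig",
    "PipelineConfig",
    "load_config",
    "dump_config",
]


class ConfigError(ValueError):
    """Invalid or out-of-range configuration value."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SynthesisConfig:
    """Parameters of the synthetic germband generator.

    The tissue is a honeycomb mesh of ``n_parasegments * parasegment_width_cells``
    cell columns by ``n_rows`` rows.  Interface disorder is angular: each AP
    (DV-oriented) interface is rotated by a wrapped-normal angle with standard
    deviation sigma(t) = sigma0 + sigma1 * max(t, 0) degrees; ground-truth PSB
    interfaces use the (1 - beta)-reduced deviation, so beta = 1 with
    sigma0 = 0 gives perfectly DV-aligned (90 deg) boundaries.
    """

    n_parasegments: int = 5
    parasegment_width_cells: int = 4
    n_rows: int = 10
    en_stripe_width: int = 1
    cell_radius: float = 10.0  # hexagon edge length, px

    beta: float = 0.9  # boundary tension in [0, 1]
    sigma0: float = 35.0  # angular jitter sd at t <= 0, degrees
    sigma1: float = 0.7  # angular jitter growth, degrees / min
    initial_alignment: bool = True  # mesoderm-pull emulation for t < 0
    psb_relax_min: float = 15.0  # minutes over which PSBs straighten after t=0
    vertex_jitter_frac: float = 0.08  # positional jitter, fraction of R per 90 deg of sigma

    t_start: float = -10.0  # min relative to extension onset
    t_end: float = 50.0
    dt: float = 1.0

    # transcription-dot model (nuclear MS2/MCP-like reporter dots)
    p_on: float = 0.9  # per-frame probability an en-positive cell shows a dot
    dot_base_intensity: float = 100.0
    parity_brightness_ratio: float = 2.0  # even-parasegment dots are brighter
    dot_jitter: float = 2.0  # positional sd around the centroid, px
    dot_noise_sd: float = 5.0  # additive intensity noise
    psf_sigma: float = 1.5  # rendered spot width, px

    seed: int = 0

    def validate(self) -> "SynthesisConfig":
        _require(self.n_parasegments >= 1, "n_parasegments must be >= 1")
        _require(self.parasegment_width_cells >= 2, "parasegment_width_cells must be >= 2")
        _require(1 <= self.en_stripe_width < self.parasegment_width_cells,
                 "en_stripe_width must be in [1, parasegment_width_cells)")
        _require(self.n_rows >= 1, "n_rows must be >= 1")
        _require(self.cell_radius > 0, "cell_radius must be positive")
        _require(0.0 <= self.beta <= 1.0, "beta must lie in [0, 1]")
        for name in ("sigma0", "sigma1", "vertex_jitter_frac", "dot_jitter",
                     "dot_noise_sd", "psf_sigma"):
            v = getattr(self, name)
            _require(v >= 0 and v == v, f"{name} must be finite and >= 0")
        _require(self.t_end >= self.t_start, "t_end must not precede t_start")
        _require(self.dt > 0, "dt must be positive")
        _require(0.0 <= self.p_on <= 1.0, "p_on must lie in [0, 1]")
        _require(self.parity_brightness_ratio >= 1.0,
                 "parity_brightness_ratio must be >= 1 (even stripes are the brighter ones)")
        return self

    @property
    def n_columns(self) -> int:
        return self.n_parasegments * self.parasegment_width_cells

    @property
    def frame_times(self) -> list[float]:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return [self.t_start + i * self.dt for i in range(n)]


@dataclass
class TraceSetConfig:
    """Parameters of the synthetic interface line-trace generator.

    Each pair is a (PSB, +1 control) trace; the PSB signal pixels carry
    ``enrichment_factor`` times the control signal level, emulating cortical
    Myosin II enrichment, and ``background_fraction`` of pixels sit at the
    background level.
    """

    n_pairs: int = 50
    enrichment_factor: float = 1.5
    background_fraction: float = 0.2
    background_level: float = 0.0
    signal_level: float = 100.0
    noise_sd: float = 5.0
    trace_length: int = 50  # pixels
    wiggle_sd: float = 0.0  # lateral sd of the trace polyline, px
    division_flag_prob: float = 0.0
    seed: int = 0

    def validate(self) -> "TraceSetConfig":
        _require(self.n_pairs >= 1, "n_pairs must be >= 1")
        _require(self.enrichment_factor > 0, "enrichment_factor must be > 0")
        _require(0.0 <= self.background_fraction < 1.0,
                 "background_fraction must lie in [0, 1)")
        _require(self.trace_length >= 2, "trace_length must be >= 2")
        _require(self.background_fraction * self.trace_length >= 1,
                 "background_fraction * trace_length must be >= 1 pixel")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(0.0 <= self.division_flag_prob <= 1.0,
                 "division_flag_prob must lie in [0, 1]")
        return self


@dataclass
class ScreenFixtureConfig:
    """Venn-region sizes and annotation noise for the in-silico screen fixture.

    Region names follow the three criteria: striped expression (S), surface
    protein (U), pair-rule regulated (P).
    """

    only_striped: int = 20
    only_surface: int = 30
    only_pairrule: int = 25
    striped_surface: int = 8
    striped_pairrule: int = 6
    surface_pairrule: int = 9
    all_three: int = 7
    n_aliases: int = 10  # symbols replaced by an alias in the criterion lists
    frac_low_early: float = 0.2  # genes with < 5% of expression before 6 h AEL
    frac_not_striped_by_eye: float = 0.1
    frac_non_surface_role: float = 0.1
    seed: int = 0

    def validate(self) -> "ScreenFixtureConfig":
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("only_", "striped_", "surface_", "all_", "n_")):
                _require(int(v) == v and v >= 0, f"{f.name} must be a non-negative count")
        for name in ("frac_low_early", "frac_not_striped_by_eye", "frac_non_surface_role"):
            _require(0.0 <= getattr(self, name) <= 1.0, f"{name} must lie in [0, 1]")
        _require(self.n_aliases <= self.n_genes, "n_aliases cannot exceed the gene count")
        return self

    @property
    def n_genes(self) -> int:
        return (self.only_striped + self.only_surface + self.only_pairrule
                + self.striped_surface + self.striped_pairrule
                + self.surface_pairrule + self.all_three)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate -> track -> classify -> stats)."""

    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    traces: TraceSetConfig = field(default_factory=TraceSetConfig)
    screen: ScreenFixtureConfig = field(default_factory=ScreenFixtureConfig)

    # dot handling
    capture_radius: float = 5.0  # px, for dots just outside every polygon
    max_displacement: float = 8.0  # px, dot linking
    max_gap: int = 1  # frames a track may bridge
    min_frames_expressing: int = 3
    parity_ratio_threshold: float = 1.5

    # co-alignment statistics
    coalign_threshold_deg: float = 60.0
    loess_span: float = 0.75
    t_test_min: float = 30.0
    t_window_halfwidth: float = 1.0
    window: tuple[float, float] = (-10.0, 50.0)

    # fixed-embryo quantification
    background_fraction: float = 0.2

    # screen
    early_fraction_threshold: float = 0.05

    make_plots: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        self.synthesis.validate()
        self.traces.validate()
        self.screen.validate()
        _require(self.capture_radius >= 0, "capture_radius must be >= 0")
        _require(self.max_displacement > 0, "max_displacement must be > 0")
        _require(self.min_frames_expressing >= 1, "min_frames_expressing must be >= 1")
        _require(0 < self.loess_span <= 1.0, "loess_span must lie in (0, 1]")
        _require(0 < self.background_fraction < 1, "background_fraction must lie in (0, 1)")
        return self


_SECTIONS = {"synthesis": SynthesisConfig, "traces": TraceSetConfig,
             "screen": ScreenFixtureConfig}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; unknown keys raise ConfigError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            bad = set(val) - names
            _require(not bad, f"unknown keys in '{key}': {sorted(bad)}")
            kwargs[key] = cls(**val)
        else:
            names = {f.name for f in dataclasses.fields(PipelineConfig)}
            _require(key in names, f"unknown config key: {key!r}")
            kwargs[key] = tuple(val) if key == "window" else val
    return PipelineConfig(**kwargs).validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialize the effective configuration next to the run's outputs."""
    d = dataclasses.asdict(cfg)
    d["window"] = list(d["window"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
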