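"""Publication-style plots: co-alignment curves and kymographs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_coalignment_curves", "plot_kymograph"]

_COLORS = {"psb": "#d62728", "minus1": "#1f77b4", "plus1": "#2ca02c"}


def plot_coalignment_curves(curves: pd.DataFrame, path: str | Path,
                            threshold: float = 60.0) -> None:
    """Proportion of interfaces > threshold deg vs time, LOESS curve + 95% band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in curves.groupby("condition"):
        sub = sub.sort_values("time_min")
        color = _COLORS.get(cond, "gray")
        ax.scatter(sub.time_min, sub.proportion, s=10, alpha=0.5, color=color)
        ax.plot(sub.time_min, sub.loess_fit, color=color, label=cond)
        ax.fill_between(sub.time_min, sub.ci_lo, sub.ci_hi, color=color, alpha=0.2)
    ax.set_xlabel("time relative to extension onset (min)")
    ax.set_ylabel(f"proportion of interfaces > {threshold:.0f}\N{DEGREE SIGN} from AP")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kymograph(kymo: np.ndarray, edges: np.ndarray, frames: np.ndarray,
                   path: str | Path, label: str = "dot count") -> None:
    """AP position x time heat map of transcription dots."""
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [frames.min() if len(frames) else 0, frames.max() if len(frames) else 1,
              edges[0], edges[-1]]
    im = ax.imshow(kymo, aspect="auto", origin="lower", extent=extent, cmap="inferno")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("frame")
    ax.set_ylabel("AP position (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
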