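"""Interface co-alignment statistics over time.

Interface orientations theta (degrees from the AP axis, in [0, 180)) are
reflected about 90 deg to [0, 90] (0 = AP-aligned, 90 = DV-aligned).  The
co-alignment of a set of interfaces is the proportion with reflected angle
in [60, 90] deg; boundary straightening appears as this proportion staying
high for PSBs while control interface columns decay during axis extension.
Per-timepoint proportions are smoothed with LOESS (span 0.75) and conditions
are compared with two-sample Kolmogorov-Smirnov tests on the reflected
angle distributions, conventionally at t = 30 min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loess import loess

log = logging.getLogger(__name__)

__all__ = [
    "reflect_angles",
    "coalignment_proportion",
    "timecourse_with_loess",
    "ks_compare",
    "compare_conditions",
    "significance_stars",
    "KSResult",
    "CONDITIONS",
]

CONDITIONS = ("psb", "minus1", "plus1")


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int

    @property
    def stars(self) -> str:
        return significance_stars(self.pvalue)


def significance_stars(p: float) -> str:
    """Conventional annotation: ns (P>0.05), * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def reflect_angles(angles) -> np.ndarray:
    """Reflect orientations in [0, 180) about 90 deg: theta' = min(theta, 180-theta)."""
    a = np.asarray(angles, dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a >= 180.0):
        raise ValueError("angles must be finite and lie in [0, 180)")
    return np.minimum(a, 180.0 - a)


def coalignment_proportion(reflected, threshold: float = 60.0) -> float:
    """Fraction of reflected angles >= threshold (inclusive: [60, 90] band)."""
    a = np.asarray(reflected, dtype=float)
    if a.size == 0:
        raise ValueError("cannot compute a proportion of an empty angle sample")
    return float(np.mean(a >= threshold))


def timecourse_with_loess(samples: pd.DataFrame, span: float = 0.75,
                          threshold: float = 60.0,
                          window: tuple[float, float] = (-10.0, 50.0)) -> pd.DataFrame:
    """Per-minute co-alignment proportions with a LOESS curve and 95% band.

    ``samples`` needs columns time_min and theta_deg (raw orientations).
    Times are binned to the nearest minute inside ``window`` before fitting.
    Returns columns: time_min, n_interfaces, proportion, loess_fit, ci_lo, ci_hi.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    df = samples.copy()
    df["t_bin"] = np.round(df["time_min"]).astype(int)
    df = df[(df.t_bin >= window[0]) & (df.t_bin <= window[1])]
    rows = []
    for t, sub in df.groupby("t_bin"):
        refl = reflect_angles(sub.theta_deg.to_numpy())
        rows.append({"time_min": float(t), "n_interfaces": len(sub),
                     "proportion": coalignment_proportion(refl, threshold)})
    out = pd.DataFrame(rows).sort_values("time_min").reset_index(drop=True)
    if len(out) < 3:
        raise ValueError("need at least 3 timepoints for the smoothed curve")
    fit = loess(out.time_min.to_numpy(), out.proportion.to_numpy(), span=span)
    lo, hi = fit.band()
    out["loess_fit"] = fit.fitted
    out["ci_lo"] = lo
    out["ci_hi"] = hi
    return out


def ks_compare(sample_a, sample_b, method: str = "asymp") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test on reflected angle distributions.

    D is the sup-norm distance between the two empirical cumulative
    distributions; the p-value is asymptotic by default (``method="exact"``
    for small samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                    n_a=a.size, n_b=b.size)


def compare_conditions(interfaces: pd.DataFrame, t_test: float = 30.0,
                       t_halfwidth: float = 1.0, span: float = 0.75,
                       threshold: float = 60.0,
                       window: tuple[float, float] = (-10.0, 50.0),
                       ks_method: str = "asymp") -> dict:
    """Condition curves plus pairwise KS tests at the test timepoint.

    ``interfaces`` is a tidy table with columns cls (psb/minus1/plus1/...),
    time_min and theta_deg.  Returns {"curves": tidy DataFrame,
    "ks": {(a, b): KSResult}, "t_test": t_test}; conditions missing at the
    test timepoint produce a partial report with a warning.
    """
    curves = []
    at_t: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        sub = interfaces[interfaces.cls == cond]
        if sub.empty:
            log.warning("condition %s absent from the interface table", cond)
            continue
        c = timecourse_with_loess(sub, span=span, threshold=threshold, window=window)
        c.insert(0, "condition", cond)
        curves.append(c)
        m = np.abs(sub.time_min - t_test) <= t_halfwidth
        if m.any():
            at_t[cond] = reflect_angles(sub.loc[m, "theta_deg"].to_numpy())
        else:
            log.warning("condition %s has no interfaces at t = %g +/- %g min",
                        cond, t_test, t_halfwidth)
    ks = {}
    names = list(at_t)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ks[(names[i], names[j])] = ks_compare(at_t[names[i]], at_t[names[j]],
                                                  method=ks_method)
    return {"curves": pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
            "ks": ks, "t_test": t_test}


def ks_report_table(ks: dict, t_test: float) -> pd.DataFrame:
    """Flatten pairwise KS results for CSV export."""
    rows = [{"time_min": t_test, "condition_a": a, "condition_b": b,
             "D": r.statistic, "pvalue": r.pvalue, "n_a": r.n_a, "n_b": r.n_b,
             "significance": r.stars}
            for (a, b), r in ks.items()]
    return pd.DataFrame(rows, columns=["time_min", "condition_a", "condition_b",
                                       "D", "pvalue", "n_a", "n_b", "significance"])
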