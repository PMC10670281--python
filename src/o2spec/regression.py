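"""Linear dose-response and efficacy regression with outlier bookkeeping.

Used for the 1O2-vs-excitation-intensity dose curves and the tumor-reduction
efficacy correlation: ordinary least squares, R-squared, per-group mean/SD
summaries, and explicit (never silent) outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "linear_fit",
    "exclude_outliers",
    "summarize_with_sd",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_included: int
    n_excluded: int
    excluded_indices: tuple[int, ...]
    residual_sd: float
    stderr_slope: float = float("nan")


def linear_fit(x, y, exclude_indices=()) -> RegressionResult:
    """Ordinary least-squares line through the included points.

    R^2 = 1 - SS_res/SS_tot over the included points; undefined (NaN, with a
    raised error suppressed into the field) when y has no variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    excl = sorted(set(int(i) for i in exclude_indices))
    keep = np.ones(x.size, dtype=bool)
    if excl:
        keep[excl] = False
    xi, yi = x[keep], y[keep]
    if xi.size < 2:
        raise ValueError("need >= 2 included points for a linear fit")
    if np.ptp(xi) == 0:
        raise ValueError("x has zero variance among included points")
    res = stats.linregress(xi, yi)
    yhat = res.intercept + res.slope * xi
    ss_res = float(((yi - yhat) ** 2).sum())
    ss_tot = float(((yi - yi.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = max(xi.size - 2, 1)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_included=int(xi.size),
        n_excluded=len(excl),
        excluded_indices=tuple(excl),
        residual_sd=float(np.sqrt(ss_res / dof)),
        stderr_slope=float(res.stderr),
    )


def exclude_outliers(x, y, rule="manual", manual_indices=(), threshold: float = 3.0):
    """Indices to exclude before fitting.

    ``manual`` passes the user's list through untouched -- the default,
    because exclusions in this setting are typically knowledge-based
    (e.g. subject motion), not statistical.  ``studentized`` flags points
    whose externally studentized residual exceeds ``threshold``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return []
    if rule == "manual":
        return sorted(set(int(i) for i in manual_indices))
    if rule != "studentized":
        raise ValueError(f"unknown outlier rule {rule!r}")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if x.size < 4:
        return []
    flagged = []
    for i in range(x.size):
        keep = np.ones(x.size, dtype=bool)
        keep[i] = False
        res = stats.linregress(x[keep], y[keep])
        pred = res.intercept + res.slope * x[i]
        resid = y[keep] - (res.intercept + res.slope * x[keep])
        s = np.sqrt((resid**2).sum() / max(keep.sum() - 2, 1))
        dev = abs(y[i] - pred)
        # s == 0 means the remaining points are exactly collinear: any
        # deviation at all is then infinitely studentized
        if dev / s > threshold if s > 0 else dev > 0:
            flagged.append(i)
    return flagged


def summarize_with_sd(groups: dict) -> dict:
    """Per-group mean and sample SD (n-1 denominator) for error bars.

    Single-value groups report SD 0.0 with an ``sd_undefined`` flag rather
    than NaN, so downstream plotting degrades gracefully.
    """
    out = {}
    for name, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        entry = {"mean": float(v.mean()), "n": int(v.size)}
        if v.size == 1:
            entry["sd"] = 0.0
            entry["sd_undefined"] = True
        else:
            entry["sd"] = float(v.std(ddof=1))
            entry["sd_undefined"] = False
        out[name] = entry
    return out
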