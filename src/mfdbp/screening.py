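"""Monotonic-association screening and smoothing-based breakpoint initialisation.

Two jobs run before any model is fitted.  First, Spearman rank correlations
of every morphometric variable with age flag which variables track disease
progression at all.  Second, a moving-average curve and a LOESS smooth of
MFD against age locate the region of steepest decline, providing a
data-driven starting value for the segmented regression.

The LOESS smoothing span is chosen objectively: each candidate span is fitted
and evaluated at the abscissae of the k=2 moving-average curve, and the span
minimising the RMSE against that curve wins.  Local slopes come from central
differences on a uniform age grid, re-smoothed with half the selected span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, SchemaError

__all__ = [
    "CorrelationTable",
    "SmoothCurve",
    "spearman_screen",
    "moving_average",
    "loess_smooth",
    "fit_loess_with_span_selection",
    "candidate_breakpoint",
]

#: Variables screened by default (all Table-style morphometric columns).
DEFAULT_SCREEN_VARIABLES = [
    "mean_mfs_um2",
    "sd_mfs_um2",
    "cov_mfs",
    "mfd_fibres_mm2",
    "mfa_pct",
    "fat_pct",
    "cfa_pct",
]


@dataclass
class CorrelationTable:
    """Spearman correlations of each variable with age."""

    table: pd.DataFrame  # index: variable; columns: rho, p_value, n

    def rho(self, variable: str) -> float:
        return float(self.table.loc[variable, "rho"])

    def rounded(self) -> pd.DataFrame:
        """Two-decimal display convention for correlation coefficients."""
        out = self.table.copy()
        out["rho"] = out["rho"].round(2)
        return out


@dataclass
class SmoothCurve:
    """A smoothed response curve on an ascending age grid."""

    grid: np.ndarray
    value: np.ndarray
    local_slope: np.ndarray | None = None
    span_or_k: float | None = None
    rmse_by_span: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if np.any(np.diff(self.grid) < 0):
            raise ValueError("grid must be ascending")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("smoothed values must be finite")


def spearman_screen(cohort: Cohort, variables: Sequence[str] | None = None) -> CorrelationTable:
    """Spearman rank correlation of each variable with age at biopsy.

    Ties receive average ranks; p-values come from the standard large-sample
    t approximation.  Requires at least 3 complete observations per variable.
    """
    variables = list(variables) if variables is not None else list(DEFAULT_SCREEN_VARIABLES)
    rows = []
    ages = cohort.ages
    for var in variables:
        vals = cohort.variable(var)  # raises SchemaError for unknown names
        mask = np.isfinite(vals) & np.isfinite(ages)
        if mask.sum() < 3:
            raise ValueError(f"variable {var!r} has fewer than 3 observations")
        res = stats.spearmanr(ages[mask], vals[mask])
        rows.append({"variable": var, "rho": res.statistic, "p_value": res.pvalue, "n": int(mask.sum())})
    table = pd.DataFrame(rows).set_index("variable")
    return CorrelationTable(table=table)


def moving_average(x: np.ndarray, y: np.ndarray, k: int) -> SmoothCurve:
    """Centred moving mean over ``k`` consecutive points ordered by ``x``.

    The curve is indexed by the mean age of each window, so a window over
    points i..i+k-1 contributes one (mean age, mean response) pair.
    ``k=1`` is the identity on the data points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not 1 <= k <= n:
        raise ValueError(f"window size k={k} outside 1..{n}")
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    kernel = np.ones(k) / k
    gx = np.convolve(xs, kernel, mode="valid")
    gy = np.convolve(ys, kernel, mode="valid")
    return SmoothCurve(grid=gx, value=gy, span_or_k=k)


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    xeval: np.ndarray,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    For each evaluation point the nearest ``ceil(span * n)`` observations get
    tricube weights scaled by the span radius, and a weighted polynomial of
    the given degree is fitted and evaluated there.  Degree 2 is the default;
    it is the classic scatterplot-smoother choice and, on the reference
    cohort, the one under which the objective span selection lands on 0.30.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xeval = np.asarray(xeval, dtype=float)
    n = len(x)
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    q = min(n, max(degree + 2, int(np.ceil(span * n))))
    out = np.empty(len(xeval))
    for j, x0 in enumerate(xeval):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            h = d.max() if d.max() > 0 else 1.0
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        m = w > 0
        if not np.any(m):
            raise FloatingPointError(f"all-zero weights at span {span} (x0={x0})")
        X = np.vander(x[m] - x0, degree + 1, increasing=True)
        XtW = X.T * w[m]
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ y[m])
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"degenerate local fit at span {span} (x0={x0})") from exc
        out[j] = beta[0]
    return out


def fit_loess_with_span_selection(
    x: np.ndarray,
    y: np.ndarray,
    candidate_spans: Sequence[float] | None = None,
    reference_k: int = 2,
    degree: int = 2,
    grid_points: int = 200,
) -> SmoothCurve:
    """LOESS curve with the span chosen by RMSE against a moving average.

    Every candidate span is fitted and evaluated at the abscissae of the
    ``k=reference_k`` moving-average curve; the span with the smallest RMSE
    against that curve is selected.  The winning curve is then evaluated on
    a uniform ``grid_points``-point age grid; its local slope is estimated
    by central differences and re-smoothed with half the selected span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("span selection needs at least 10 points")
    if candidate_spans is None:
        candidate_spans = np.round(np.arange(0.20, 0.901, 0.05), 2)
    ma = moving_average(x, y, reference_k)
    rmse_by_span: dict[float, float] = {}
    for span in candidate_spans:
        fitted = loess_smooth(x, y, span, ma.grid, degree=degree)
        rmse_by_span[float(span)] = float(np.sqrt(np.mean((fitted - ma.value) ** 2)))
    best_span = min(rmse_by_span, key=rmse_by_span.get)

    grid = np.linspace(x.min(), x.max(), grid_points)
    value = loess_smooth(x, y, best_span, grid, degree=degree)
    raw_slope = np.gradient(value, grid)
    slope = loess_smooth(grid, raw_slope, best_span / 2.0, grid, degree=1)
    return SmoothCurve(
        grid=grid, value=value, local_slope=slope, span_or_k=best_span, rmse_by_span=rmse_by_span
    )


def candidate_breakpoint(curve: SmoothCurve) -> float:
    """Age at which the smoothed local slope is most negative.

    This is the "steepest decline" initialiser for the segmented fit.  The
    contract is the argmin of the slope regardless of sign; if no slope is
    negative a warning is emitted but the minimising age is still returned.
    """
    if curve.local_slope is None:
        raise ValueError("curve carries no local slope estimate")
    slope = np.asarray(curve.local_slope)
    if np.all(slope >= 0):
        import warnings

        warnings.warn("no declining region found; returning argmin of slope anyway")
    return float(curve.grid[int(np.argmin(slope))])
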