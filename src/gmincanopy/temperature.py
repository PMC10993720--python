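"""Temperature response of minimum conductance: exponential and segmented fits.

Minimum conductance rises with temperature; the pooled species data are
summarised by an exponential model

    g_min(T) = a * exp(b * T)

fitted by nonlinear least squares (initialised from a log-linear OLS fit).
Several species additionally show a phase-transition temperature above which
g_min rises much more steeply, attributed to a structural change of the
cuticular waxes.  That breakpoint is located with a continuous two-segment
(bi-linear) regression: grid search over interior candidate temperatures at
0.1 degC resolution, golden-section refinement, an F-test of the two-segment
model against a single line for significance, and a seeded nonparametric
bootstrap for the breakpoint's standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ExpFit",
    "BreakpointFit",
    "fit_exponential",
    "predict_gmin",
    "fit_segmented",
    "fold_change",
]


@dataclass
class ExpFit:
    """Exponential temperature response g_min(T) = a * exp(b * T)."""

    a: float  # scale, mmol m-2 s-1
    b: float  # rate, per degC
    n: int
    rss: float
    t_range: tuple[float, float]

    def predict(self, temperature):
        return self.a * np.exp(self.b * np.asarray(temperature, dtype=float))


@dataclass
class BreakpointFit:
    """Continuous bi-linear fit with a single interior breakpoint."""

    t_break: float | None  # degC; None when no interior breakpoint exists
    slope_low: float
    slope_high: float
    intercept: float
    t_break_se: float | None
    p_value: float
    converged: bool
    n: int
    rss_segmented: float
    rss_line: float

    @property
    def significant(self) -> bool:
        return self.converged and self.p_value < 0.05

    def predict(self, temperature):
        t = np.asarray(temperature, dtype=float)
        if self.t_break is None:
            return self.intercept + self.slope_low * t
        return (
            self.intercept
            + self.slope_low * t
            + (self.slope_high - self.slope_low) * np.maximum(t - self.t_break, 0.0)
        )


def fold_change(g_low: float, g_high: float) -> float:
    """Ratio g_high/g_low, e.g. conductance at 50 degC over conductance at 25 degC."""
    if g_low <= 0:
        raise ValueError("g_low must be positive")
    return g_high / g_low


def fit_exponential(temperature, gmin) -> ExpFit:
    """Least-squares fit of g_min = a*exp(b*T) to pooled observations.

    Requires observations at >= 4 distinct temperatures.  The optimiser is
    started from the log-linear OLS solution; if the nonlinear refinement
    fails to converge a ValueError carrying the log-linear fallback is raised.
    """
    t = np.asarray(temperature, dtype=float)
    g = np.asarray(gmin, dtype=float)
    if t.shape != g.shape:
        raise ValueError("temperature and gmin must have equal length")
    if np.any(g <= 0):
        raise ValueError("gmin observations must be positive")
    if np.unique(t).size < 4:
        raise ValueError("need observations at >= 4 distinct temperatures")

    # log-linear initialisation: log g = log a + b*T
    b0, log_a0 = np.polyfit(t, np.log(g), 1)
    p0 = (float(np.exp(log_a0)), float(b0))
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.exp(b * x), t, g, p0=p0, maxfev=10000
        )
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise ValueError(
            f"exponential fit did not converge; log-linear fallback a={p0[0]:.4g}, "
            f"b={p0[1]:.4g}"
        ) from err
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((g - a * np.exp(b * t)) ** 2))
    return ExpFit(a=a, b=b, n=t.size, rss=rss, t_range=(float(t.min()), float(t.max())))


def predict_gmin(fit: ExpFit, temperature):
    """Evaluate an exponential temperature-response fit (mmol m-2 s-1)."""
    out = fit.predict(temperature)
    if np.ndim(temperature) == 0:
        return float(out)
    return out


def _bilinear_rss(t, g, c):
    """OLS RSS of the continuous two-segment model with breakpoint at c."""
    x = np.column_stack([np.ones_like(t), t, np.maximum(t - c, 0.0)])
    coef, res, rank, _ = np.linalg.lstsq(x, g, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        rss = float(np.sum((g - x @ coef) ** 2))
    return rss, coef


def fit_segmented(
    temperature,
    gmin,
    grid_step: float = 0.1,
    edge_margin: float = 0.10,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BreakpointFit:
    """Continuous two-segment linear fit with a searched breakpoint.

    The breakpoint is located by exhaustive search over interior candidate
    temperatures (``edge_margin`` of the observed range excluded at each end)
    at ``grid_step`` resolution, then refined by golden-section minimisation.
    Significance is an F-test of the two-segment model (4 parameters) against
    a single line (2 parameters).  The breakpoint SE comes from a seeded
    nonparametric bootstrap (``n_boot`` resamples; 0 disables it).

    A best breakpoint landing on the grid edge yields a 'no interior
    breakpoint' result (``t_break=None``, ``converged=False``) rather than an
    exception.
    """
    t = np.asarray(temperature, dtype=float)
    g = np.asarray(gmin, dtype=float)
    if t.shape != g.shape:
        raise ValueError("temperature and gmin must have equal length")
    if t.size < 6 or np.unique(t).size < 4:
        raise ValueError("need >= 6 observations spanning >= 4 distinct temperatures")

    t_lo, t_hi = float(t.min()), float(t.max())
    span = t_hi - t_lo
    lo = t_lo + edge_margin * span
    hi = t_hi - edge_margin * span
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    # single-line reference model
    line_coef = np.polyfit(t, g, 1)
    rss_line = float(np.sum((g - np.polyval(line_coef, t)) ** 2))
    tss = float(np.sum((g - g.mean()) ** 2))

    rss_grid = np.array([_bilinear_rss(t, g, c)[0] for c in grid])
    i_best = int(np.argmin(rss_grid))

    def _null_result() -> BreakpointFit:
        return BreakpointFit(
            t_break=None,
            slope_low=float(line_coef[0]),
            slope_high=float(line_coef[0]),
            intercept=float(line_coef[1]),
            t_break_se=None,
            p_value=1.0,
            converged=False,
            n=t.size,
            rss_segmented=rss_line,
            rss_line=rss_line,
        )

    # a single line already fitting to machine precision leaves no breakpoint
    # evidence: skip the F-test rather than compare round-off residuals
    if i_best in (0, rss_grid.size - 1) or rss_line <= 1e-12 * max(tss, 1e-300):
        return _null_result()

    # golden-section refinement between the grid neighbours of the minimum
    bracket_lo, bracket_hi = grid[i_best - 1], grid[i_best + 1]
    res = optimize.minimize_scalar(
        lambda c: _bilinear_rss(t, g, c)[0],
        bounds=(bracket_lo, bracket_hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    c_best = float(res.x)
    rss_seg, coef = _bilinear_rss(t, g, c_best)
    if rss_seg > rss_grid[i_best]:  # refinement should never hurt
        c_best = float(grid[i_best])
        rss_seg, coef = _bilinear_rss(t, g, c_best)

    # F-test: the segmented model spends 2 extra parameters (slope change and
    # breakpoint location); anticonservative because the breakpoint is searched.
    df1, df2 = 2, t.size - 4
    if df2 <= 0 or rss_seg <= 0:
        p_value = 0.0
    else:
        f = ((rss_line - rss_seg) / df1) / (rss_seg / df2)
        p_value = float(stats.f.sf(max(f, 0.0), df1, df2))

    t_break_se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = []
        idx = np.arange(t.size)
        for _ in range(n_boot):
            take = rng.choice(idx, size=t.size, replace=True)
            tb, gb = t[take], g[take]
            if np.unique(tb).size < 4:
                continue
            b_lo = tb.min() + edge_margin * (tb.max() - tb.min())
            b_hi = tb.max() - edge_margin * (tb.max() - tb.min())
            b_grid = np.arange(b_lo, b_hi + grid_step / 2, grid_step)
            if b_grid.size < 3:
                continue
            b_rss = [_bilinear_rss(tb, gb, c)[0] for c in b_grid]
            j = int(np.argmin(b_rss))
            if j in (0, len(b_rss) - 1):
                continue
            boot.append(b_grid[j])
        if len(boot) > 1:
            t_break_se = float(np.std(boot, ddof=1))

    return BreakpointFit(
        t_break=c_best,
        slope_low=float(coef[1]),
        slope_high=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        t_break_se=t_break_se,
        p_value=p_value,
        converged=True,
        n=t.size,
        rss_segmented=rss_seg,
        rss_line=rss_line,
    )
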