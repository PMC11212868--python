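"""Loess smoothing and continuous two-segment (breakpoint) regression.

Used to characterise the biphasic dependence of nuclear aspect ratio on
perinuclear microtubule enrichment: a locally weighted linear (loess)
smoother with a pointwise standard-error band, and a continuous piecewise
linear least-squares fit whose breakpoint is found by grid search, with
per-segment slope t-tests (the upper segment is called "flat" when its
slope is not distinguishable from zero at p > 0.05).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SPAN = 0.75
BREAKPOINT_GRID = 200
QUANTILE_RANGE = (0.05, 0.95)


@dataclass
class LoessCurve:
    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray          # pointwise standard error of the local fit

    @property
    def band(self):
        return self.fitted - self.se, self.fitted + self.se


@dataclass
class BiphasicFit:
    breakpoint: float
    slope_below: float
    slope_above: float
    intercept_below: float            # value of the fit at the breakpoint
    slope_se_below: float
    slope_se_above: float
    slope_p_below: float
    slope_p_above: float
    residual_sd: float
    n_points: int
    flat_above: bool                  # upper-segment slope p > 0.05
    sse: float
    loess_curve: LoessCurve | None = field(default=None, repr=False)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        d = x - self.breakpoint
        return self.intercept_below + np.where(
            d < 0, self.slope_below * d, self.slope_above * d)


def loess_fit(x, y, span: float = DEFAULT_SPAN, grid=None) -> LoessCurve:
    """Locally weighted linear regression with tricube weights.

    At each evaluation point the ``span`` fraction of nearest points is fit
    by weighted least squares (degree 1); the band is +-1 SE from the local
    weighted-regression variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("loess_fit needs at least 10 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < 4:
        raise ValueError("span too small: local neighborhoods need >= 4 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)

    fitted = np.empty_like(grid)
    se = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            fitted[i] = y[idx].mean()
            se[i] = 0.0
            continue
        w = (1 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        X = np.column_stack([np.ones(k), x[idx] - x0])
        WX = X * w[:, None]
        A = X.T @ WX
        b = WX.T @ y[idx]
        beta = np.linalg.solve(A, b)
        fitted[i] = beta[0]
        resid = y[idx] - X @ beta
        dof = max(w.sum() ** 2 / (w ** 2).sum() - 2.0, 1.0)
        s2 = (w * resid ** 2).sum() / w.sum() / dof * k / max(k - 2, 1)
        # variance of the local intercept: e1' (X'WX)^-1 X'W^2X (X'WX)^-1 e1 * sigma2
        Ainv = np.linalg.inv(A)
        V = Ainv @ (X.T @ (X * (w ** 2)[:, None])) @ Ainv
        sigma2 = (w * resid ** 2).sum() / w.sum()
        se[i] = np.sqrt(max(V[0, 0] * sigma2 * k / max(k - 2, 1), 0.0))
    return LoessCurve(x=grid, fitted=fitted, se=se)


def _continuous_fit_sse(x, y, b):
    """Continuous two-segment LS fit at fixed breakpoint b.

    Basis: [1, min(x-b, 0), max(x-b, 0)]; returns (sse, beta)."""
    d = x - b
    X = np.column_stack([np.ones_like(x), np.minimum(d, 0.0), np.maximum(d, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def _segment_slope_test(x, y, slope, level):
    """Per-segment t-test of slope = 0 with segment-local residual variance."""
    n = len(x)
    if n < 3:
        return np.nan, np.nan
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        return np.nan, np.nan
    resid = y - (level + slope * x)
    resid -= resid.mean()
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(se), float(p)


def piecewise_linear_fit(points, continuity: bool = True,
                         n_grid: int = BREAKPOINT_GRID,
                         with_loess: bool = False,
                         span: float = DEFAULT_SPAN,
                         refine: bool = True) -> BiphasicFit:
    """Continuous two-segment least-squares fit with grid-searched breakpoint.

    The breakpoint is chosen among ``n_grid`` candidates spanning the
    interior 5th-95th quantiles of x, minimizing the total squared error of
    the continuous fit; ties break toward the smaller breakpoint, and with
    ``refine`` the winning candidate is polished by a bounded 1-D search
    between its grid neighbours (so noiseless two-segment data is recovered
    essentially exactly).  With ``continuity=False`` each side gets its own
    intercept (free-intercept variant).  Per-segment slope standard errors
    and p-values use segment-local residual variance.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in points)
    if len(x) < 10:
        raise ValueError("piecewise fit needs at least 10 points")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical")

    qlo, qhi = np.quantile(x, QUANTILE_RANGE)
    if qlo == qhi:
        raise ValueError("degenerate interior quantile range")
    candidates = np.linspace(qlo, qhi, n_grid)

    best = None
    for b in candidates:
        n_below = int(np.sum(x < b))
        if min(n_below, len(x) - n_below) < 2:
            continue
        if continuity:
            sse, beta = _continuous_fit_sse(x, y, b)
            fit = (b, beta[1], beta[2], beta[0], sse)
        else:
            below, above = x < b, x >= b
            sse = 0.0
            coef = []
            for m in (below, above):
                A = np.column_stack([np.ones(m.sum()), x[m]])
                bb, *_ = np.linalg.lstsq(A, y[m], rcond=None)
                r = y[m] - A @ bb
                sse += float(r @ r)
                coef.append(bb)
            fit = (b, coef[0][1], coef[1][1],
                   coef[0][0] + coef[0][1] * b, sse)
        # strict < keeps the smaller breakpoint on ties
        if best is None or fit[4] < best[4]:
            best = fit
    if best is None:
        raise ValueError("no candidate breakpoint leaves >= 2 points per segment")

    if refine and continuity:
        from scipy.optimize import minimize_scalar
        delta = candidates[1] - candidates[0]
        lo, hi = best[0] - delta, best[0] + delta
        res = minimize_scalar(lambda b: _continuous_fit_sse(x, y, b)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-9 * max(abs(hi), 1.0)})
        if res.fun <= best[4]:
            sse_r, beta_r = _continuous_fit_sse(x, y, float(res.x))
            best = (float(res.x), beta_r[1], beta_r[2], beta_r[0], sse_r)

    b, s_lo, s_hi, level, sse = best
    below, above = x < b, x >= b
    se_lo, p_lo = _segment_slope_test(x[below], y[below], s_lo, level - s_lo * b)
    se_hi, p_hi = _segment_slope_test(x[above], y[above], s_hi, level - s_hi * b)
    n = len(x)
    residual_sd = float(np.sqrt(sse / max(n - 4, 1)))
    curve = loess_fit(x, y, span=span) if with_loess else None
    return BiphasicFit(
        breakpoint=float(b), slope_below=float(s_lo), slope_above=float(s_hi),
        intercept_below=float(level), slope_se_below=se_lo, slope_se_above=se_hi,
        slope_p_below=p_lo, slope_p_above=p_hi, residual_sd=residual_sd,
        n_points=n, flat_above=bool(np.isnan(p_hi) or p_hi > 0.05),
        sse=float(sse), loess_curve=curve,
    )


def single_line_sse(x, y) -> float:
    """SSE of the ordinary one-line least-squares fit (nesting reference)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
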