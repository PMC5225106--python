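"""Electrolyte leakage and LT50 estimation by sigmoidal curve fitting.

Relative electrolyte leakage — conductivity before boiling over
conductivity after boiling (total lysis) — rises sigmoidally as leaf
tissue freezes.  The temperature at 50 % leakage (LT50, also called
TEL50) summarizes freezing tolerance.  A four-parameter logistic

    y(T) = A + (B - A) / (1 + exp((T - m) / s)),   s > 0

is fitted by least squares: a coarse grid over (m, s) with the
asymptotes solved linearly at each grid point, then derivative-free
simplex refinement of all four parameters.  With s > 0 leakage
increases as temperature decreases, approaching the upper asymptote B
at the cold end.  Two LT50 readings are reported: the absolute
definition (fitted curve crosses 0.5) and the curve midpoint m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = ["LeakageFit", "relative_leakage", "logistic", "fit_lt50", "fit_lt50_per_replicate"]


def relative_leakage(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive relative leakage = cond_before / cond_after per observation.

    Requires columns ``cond_before`` and ``cond_after``; ratios above 1
    are clipped to 1 with a warning, non-positive after-boiling readings
    are an error.
    """
    for col in ("cond_before", "cond_after"):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} required")
    after = raw["cond_after"].to_numpy(dtype=float)
    if np.any(after <= 0) or np.any(~np.isfinite(after)):
        bad = raw.index[(after <= 0) | ~np.isfinite(after)]
        raise ValueError(f"non-positive after-boiling conductivity at rows {list(bad)}")
    ratio = raw["cond_before"].to_numpy(dtype=float) / after
    n_over = int(np.sum(ratio > 1.0))
    if n_over:
        warnings.warn(f"{n_over} leakage ratio(s) > 1 clipped to 1", RuntimeWarning)
    out = raw.copy()
    out["relative_leakage"] = np.clip(ratio, 0.0, 1.0)
    return out


def logistic(t: np.ndarray | float, lower: float, upper: float,
             midpoint: float, scale: float) -> np.ndarray:
    """Decreasing-in-T logistic: y -> upper as T falls below the midpoint."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) / (1.0 + np.exp((t - midpoint) / scale))


@dataclass(frozen=True)
class LeakageFit:
    """Fitted logistic parameters and the derived LT50 temperatures."""

    lower: float
    upper: float
    midpoint: float
    scale: float
    lt50_absolute: float  # temperature where fitted leakage = 0.5; NaN if no crossing
    lt50_midpoint: float  # the curve midpoint m
    rss: float
    converged: bool

    @property
    def lt50(self) -> float:
        """Primary LT50: absolute 50 % crossing, midpoint as fallback."""
        return self.lt50_absolute if np.isfinite(self.lt50_absolute) else self.lt50_midpoint

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        return logistic(t, self.lower, self.upper, self.midpoint, self.scale)


def _solve_asymptotes(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (A, B) for y ~ A(1-g) + Bg at fixed gate g; returns RSS too."""
    design = np.column_stack([1.0 - g, g])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_lt50(
    temperatures: np.ndarray | pd.Series,
    leakage: np.ndarray | pd.Series | None = None,
    grid_m: int = 41,
    grid_s: int = 12,
    max_iter: int = 4000,
) -> LeakageFit:
    """Fit the 4-parameter logistic and report both LT50 definitions.

    Accepts either a tidy frame with ``temperature_C`` and
    ``relative_leakage`` columns as the first argument, or two aligned
    arrays.  The fit is deterministic for given data: grid search over
    (midpoint, scale) with closed-form asymptotes, then Nelder-Mead
    refinement.  Non-convergence is flagged, parameters still returned.
    """
    if leakage is None:
        frame = temperatures
        t = frame["temperature_C"].to_numpy(dtype=float)
        y = frame["relative_leakage"].to_numpy(dtype=float)
    else:
        t = np.asarray(temperatures, dtype=float)
        y = np.asarray(leakage, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n_temps = np.unique(t).size
    if n_temps < 5:
        raise ValueError(f"need >= 5 distinct temperatures, got {n_temps}")

    t_lo, t_hi = float(t.min()), float(t.max())
    span = t_hi - t_lo
    best = None
    for m in np.linspace(t_lo, t_hi, grid_m):
        for s in np.geomspace(0.05 * span, span, grid_s):
            g = 1.0 / (1.0 + np.exp((t - m) / s))
            a, b, rss = _solve_asymptotes(g, y)
            if best is None or rss < best[0]:
                best = (rss, a, b, m, s)
    rss0, a0, b0, m0, s0 = best

    def objective(theta: np.ndarray) -> float:
        a, b, m, log_s = theta
        resid = y - logistic(t, a, b, m, np.exp(log_s))
        return float(resid @ resid)

    res = minimize(
        objective,
        x0=np.array([a0, b0, m0, np.log(s0)]),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-10, "fatol": 1e-14},
    )
    a, b, m, log_s = res.x
    s = float(np.exp(log_s))
    rss = float(res.fun)
    converged = bool(res.success)
    if not converged:
        logger.warning("LT50 refinement did not converge: %s", res.message)
    if b < a:
        # leakage decreasing with cold is outside the model's intent
        logger.warning("fitted upper asymptote below lower; data may be inverted")

    if a < 0.5 < b:
        # solve A + (B-A)/(1+e^((T-m)/s)) = 0.5
        lt50_abs = m + s * np.log((b - 0.5) / (0.5 - a))
    else:
        lt50_abs = float("nan")
        logger.warning("fitted curve never crosses 50%% leakage; absolute LT50 unavailable")
    return LeakageFit(
        lower=float(a), upper=float(b), midpoint=float(m), scale=s,
        lt50_absolute=float(lt50_abs), lt50_midpoint=float(m),
        rss=rss, converged=converged,
    )


def fit_lt50_per_replicate(frame: pd.DataFrame) -> pd.DataFrame:
    """Fit each replicate separately; returns per-replicate LT50s plus
    their mean and standard error in the attrs dict."""
    rows = []
    for rep, sub in frame.groupby("replicate"):
        fit = fit_lt50(sub)
        rows.append({"replicate": rep, "lt50": fit.lt50,
                     "lt50_absolute": fit.lt50_absolute,
                     "lt50_midpoint": fit.lt50_midpoint, "rss": fit.rss})
    out = pd.DataFrame(rows)
    vals = out["lt50"].to_numpy()
    out.attrs["lt50_mean"] = float(np.mean(vals))
    out.attrs["lt50_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
    return out
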