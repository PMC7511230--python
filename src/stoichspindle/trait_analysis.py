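"""Trait extraction from spindle time series and the correlation /
partial-correlation machinery used to discriminate size-control models.

Spindle length traces l(t) are fit with a rising sigmoid

    l(t) = IL + (FL - IL) / (1 + exp(-(t - t0)/tau_s))

giving initial length IL, final (plateau) length FL, midpoint time t0 and
timescale tau_s; the elongation rate is the sigmoid slope at t0,
ER = (FL - IL)/(4 tau_s).  The posterior-pole-to-posterior-boundary
distance is fit with the falling counterpart whose plateau is the final
centrosome distance CD.

Trait tables (one row per simulated run or synthetic line) are analysed
with ordinary least squares and with partial correlation by residual
regression: regress both traits on the conditioning trait, then regress
the residuals on each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import Trajectory
from .geometry import CellGeometry

__all__ = [
    "SigmoidFit",
    "TraitRecord",
    "AssociationResult",
    "fit_sigmoid",
    "elongation_rate",
    "extract_traits",
    "traits_to_table",
    "regress",
    "partial_correlation",
    "model_signature_tests",
]


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter sigmoid fit of a plateauing time series.

    ``baseline`` is the early plateau, ``plateau`` the late one; for a
    falling fit (``kind='falling'``) the plateau is the *lower* late
    level (the final centrosome distance CD).
    """

    baseline: float
    plateau: float
    midpoint: float
    timescale: float
    residual_rms: float
    kind: str = "rising"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.baseline + (self.plateau - self.baseline) / (
            1.0 + np.exp(-(t - self.midpoint) / self.timescale)
        )


@dataclass
class TraitRecord:
    """Per-run spindle and cell traits (um, um/s)."""

    IL: float
    FL: float
    ER: float
    CD: float
    CL: float
    CA: float
    center_offset: float
    tau_s: float = np.nan
    t0: float = np.nan
    plateau_ok: bool = True
    line: Optional[str] = None


@dataclass(frozen=True)
class AssociationResult:
    """OLS regression y = m x + b (optionally on residuals after
    conditioning), with standard error and two-sided p-value for the
    slope, and the Pearson correlation r."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r: float
    n: int
    conditioned_on: Optional[str] = None


def _sigmoid(t, lo, hi, t0, tau):
    return lo + (hi - lo) / (1.0 + np.exp(-(t - t0) / tau))


def fit_sigmoid(times, values, kind: str = "rising") -> SigmoidFit:
    """Nonlinear least-squares sigmoid fit.

    Initialization: baseline and plateau from the first/last decile
    means, midpoint from the half-range crossing, timescale from a
    quarter of the 10-90% transition interval.  ``kind='falling'`` fits
    a decreasing series (the transition runs from the high early level
    down to the late plateau).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 8:
        raise ValueError("need at least 8 points spanning the transition")
    if kind not in ("rising", "falling"):
        raise ValueError("kind must be 'rising' or 'falling'")

    k = max(1, len(t) // 10)
    lo0 = float(np.mean(y[:k]))
    hi0 = float(np.mean(y[-k:]))
    span = hi0 - lo0
    if abs(span) < 1e-12:
        return SigmoidFit(lo0, hi0, float(np.median(t)), max(
            (t[-1] - t[0]) / 4.0, 1e-6), float(np.std(y)), kind)
    half = lo0 + 0.5 * span
    crossing = np.nonzero(np.sign(y - half) != np.sign(y[0] - half))[0]
    t0_0 = float(t[crossing[0]]) if len(crossing) else float(np.median(t))
    frac = (y - lo0) / span
    in_rise = (frac > 0.1) & (frac < 0.9)
    tau0 = max(float(np.ptp(t[in_rise])) / 4.0, (t[1] - t[0])) if in_rise.sum() > 1 else (
        (t[-1] - t[0]) / 8.0)

    p0 = (lo0, hi0, t0_0, tau0)
    # loose bounds keep the baseline/plateau near the observed range —
    # traces without an early plateau (e.g. elongation sampled from
    # anaphase onset) otherwise push the baseline to absurd values
    ymin, ymax, yspan = float(y.min()), float(y.max()), float(np.ptp(y))
    T = float(t[-1] - t[0])
    if kind == "rising":
        lo_b = (ymin - 0.2 * yspan, ymin + 0.6 * yspan)
        hi_b = (ymax - 0.6 * yspan, ymax + yspan)
    else:
        lo_b = (ymax - 0.6 * yspan, ymax + 0.2 * yspan)
        hi_b = (ymin - yspan, ymin + 0.6 * yspan)
    bounds = ([lo_b[0], hi_b[0], t[0] - 2 * T, 1e-3 * T],
              [lo_b[1], hi_b[1], t[-1] + 2 * T, 10 * T])
    p0 = tuple(np.clip(p0, bounds[0], bounds[1]))
    try:
        popt, _ = optimize.curve_fit(_sigmoid, t, y, p0=p0, bounds=bounds,
                                     maxfev=20000)
    except RuntimeError as err:
        raise ValueError(
            f"sigmoid fit did not converge (init {p0}): {err}") from err
    lo, hi, t0, tau = popt
    resid = y - _sigmoid(t, lo, hi, t0, tau)
    rms = float(np.sqrt(np.mean(resid**2)))
    return SigmoidFit(float(lo), float(hi), float(t0), float(tau), rms, kind)


def elongation_rate(fit: SigmoidFit) -> float:
    """Elongation rate at the sigmoid midpoint, ER = (FL - IL)/(4 tau_s)."""
    return (fit.plateau - fit.baseline) / (4.0 * fit.timescale)


def _plateau_reached(times, values, window_frac=0.1, tol=0.5) -> bool:
    n = max(2, int(len(values) * window_frac))
    tail = values[-n:]
    return float(np.ptp(tail)) < tol


def extract_traits(traj: Trajectory, geom: CellGeometry) -> TraitRecord:
    """Spindle and cell traits from one simulated trajectory.

    IL, FL, ER come from the rising sigmoid fit of L(t); CD from the
    falling fit of the posterior pole's distance to the posterior cell
    boundary (x = +Rx); CL = 2 Rx; CA is the midplane-section area; the
    centre offset is the final x of the spindle midpoint.
    """
    t = traj.times
    L = traj.length
    fit = fit_sigmoid(t, L, kind="rising")
    # posterior pole = larger final x
    poles = traj.positions[-1, :, 0]
    post = int(np.argmax(poles))
    dist_post = geom.Rx - traj.positions[:, post, 0]
    cd_fit = fit_sigmoid(t, dist_post, kind="falling")
    record = TraitRecord(
        IL=fit.baseline,
        FL=fit.plateau,
        ER=elongation_rate(fit),
        CD=cd_fit.plateau,
        CL=geom.cell_length,
        CA=geom.midplane_section_area(),
        center_offset=float(traj.center[-1, 0]),
        tau_s=fit.timescale,
        t0=fit.midpoint,
        plateau_ok=_plateau_reached(t, L),
    )
    return record


def traits_to_table(records: list[TraitRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def _ols(x: np.ndarray, y: np.ndarray, conditioned_on=None) -> AssociationResult:
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return AssociationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        p_value=float(res.pvalue),
        r=float(res.rvalue),
        n=n,
        conditioned_on=conditioned_on,
    )


def regress(table: pd.DataFrame, y: str, x: str) -> AssociationResult:
    """OLS of trait y on trait x with slope SE and two-sided p-value."""
    d = table[[x, y]].dropna()
    return _ols(d[x].to_numpy(float), d[y].to_numpy(float))


def partial_correlation(table: pd.DataFrame, y: str, x: str, z: str) -> AssociationResult:
    """Association of y with x conditioned on z by residual regression:
    R_y = y - (m1 z + b1), R_x = x - (m2 z + b2), then OLS of R_y on R_x."""
    d = table[[x, y, z]].dropna()
    if len(d) < 4:
        raise ValueError("need at least 4 observations for partial correlation")
    zv = d[z].to_numpy(float)
    if np.ptp(zv) == 0:
        # constant conditioner: partial == raw
        return _ols(d[x].to_numpy(float), d[y].to_numpy(float), conditioned_on=z)
    ry = d[y].to_numpy(float) - np.polyval(np.polyfit(zv, d[y], 1), zv)
    rx = d[x].to_numpy(float) - np.polyval(np.polyfit(zv, d[x], 1), zv)
    out = _ols(rx, ry, conditioned_on=z)
    return out


def model_signature_tests(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Correlation signatures of the candidate size-control models.

    - Timer: initial length and elongation are set independently, so
      FL = IL + Delta predicts corr(IL, FL) > 0.
    - Limiting Component: spindle growth exhausts a cytoplasmic pool, so
      the partial correlation of FL with cell area CA given cell length
      CL should be positive.
    - Boundary: poles stop at a fixed distance from the cortex, so
      corr(FL, CL) > 0 and corr(FL, CD) < 0.

    Returns per-model dicts with the measured associations and a
    ``consistent`` verdict at significance level alpha.
    """
    required = {"IL", "FL", "CL", "CA", "CD"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")

    timer = regress(table, "FL", "IL")
    limiting = partial_correlation(table, "FL", "CA", "CL")
    boundary_cl = regress(table, "FL", "CL")
    boundary_cd = regress(table, "FL", "CD")

    return {
        "timer": {
            "association": timer,
            "consistent": bool(timer.slope > 0 and timer.p_value < alpha),
        },
        "limiting_component": {
            "association": limiting,
            "consistent": bool(limiting.slope > 0 and limiting.p_value < alpha),
        },
        "boundary": {
            "association_cl": boundary_cl,
            "association_cd": boundary_cd,
            "consistent": bool(
                boundary_cl.slope > 0
                and boundary_cl.p_value < alpha
                and boundary_cd.slope < 0
                and boundary_cd.p_value < alpha
            ),
        },
    }
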