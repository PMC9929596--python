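"""Normalized phase-portrait pipeline and leptin-fat population fits.

A controlled-feeding experiment (Harris-type protocol: groups tube-fed a
fraction of the control intake for a fixed period, then returned to
ad-libitum feeding) measures both lines of the phase portrait.  Because
growing animals gain weight throughout, every series is first expressed in
fold change relative to the control group; the shared growth trend and any
systematic handling effect cancel.  In those coordinates:

* each controlled group contributes one **diet point** -- (mean relative
  intake during the controlled phase, relative fat at its end);
* each recovery day contributes one **appetite point** -- (relative fat,
  relative ad-libitum intake), pooled over groups.

The diet line is fitted as ``F = a*u - b`` by ordinary least squares and the
appetite line as ``F = (c/u) * (umax/u - 1)**(1/n)`` by bounded nonlinear
least squares with multiple Hill-steepness starts.  Residuals are taken in
fat units for both (the response variable of the written forms).

A leptin-fat population scatter is fitted with the no-intercept quadratic
``L = a_q*F**2 + b_q*F`` against the linear alternative ``L = c*F``; models
are compared by AIC (Gaussian-RSS form, ``N*ln(RSS/N) + 2k``) and Pearson
r-squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "FeedingExperiment",
    "PhasePortraitData",
    "DietLineFit",
    "AppetiteLineFit",
    "LeptinFatFit",
    "normalize_to_control",
    "extract_phase_points",
    "fit_diet_line",
    "fit_appetite_line",
    "fit_leptin_fat",
    "fit_phase_portrait",
    "appetite_model",
]

FEEDING_COLUMNS = ("group", "day", "intake", "fat", "weight")


@dataclass(frozen=True)
class FeedingExperiment:
    """Per-group daily series of a controlled-feeding experiment.

    ``data`` columns: group, day, intake, fat and/or weight.  The control
    group must be present; the controlled-feeding and recovery windows are
    half-open day intervals ``[start, end]`` (inclusive), disjoint and
    ordered.
    """

    data: pd.DataFrame
    control_group: str
    controlled_window: tuple[float, float]
    recovery_window: tuple[float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = {"group", "day", "intake"} - set(self.data.columns)
        if missing:
            raise ValueError(f"feeding data lacks required columns: {sorted(missing)}")
        if "fat" not in self.data.columns and "weight" not in self.data.columns:
            raise ValueError("feeding data needs a fat or weight column")
        if self.control_group not in set(self.data["group"]):
            raise ValueError(f"control group {self.control_group!r} absent from data")
        c0, c1 = self.controlled_window
        r0, r1 = self.recovery_window
        if not (c0 < c1 <= r0 < r1):
            raise ValueError("windows must be disjoint and ordered: controlled before recovery")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.data["group"]))


@dataclass(frozen=True)
class PhasePortraitData:
    """Fold-change phase-portrait point sets extracted from an experiment.

    ``diet_points``: one row per controlled group (columns group, u, F).
    ``appetite_points``: one row per (group, recovery day) (columns group,
    day, F, u).  The control group maps to (1, 1) by construction.
    """

    diet_points: pd.DataFrame
    appetite_points: pd.DataFrame


@dataclass(frozen=True)
class DietLineFit:
    """OLS fit of the diet line F = a*u - b in fold-change coordinates."""

    a: float
    b: float
    sd_a: float | None
    sd_b: float | None
    residuals: np.ndarray = field(repr=False)
    n_points: int = 0

    @property
    def sds_available(self) -> bool:
        return self.sd_a is not None


@dataclass(frozen=True)
class AppetiteLineFit:
    """Nonlinear fit of the appetite line F = (c/u)*(umax/u - 1)**(1/n)."""

    c: float
    umax: float
    n: float
    sd_c: float
    sd_umax: float
    sd_n: float
    residuals: np.ndarray = field(repr=False)
    n_points: int = 0
    n_starts_converged: int = 0


@dataclass(frozen=True)
class LeptinFatFit:
    """Quadratic (L = a_q F^2 + b_q F) vs linear (L = c F) population fit."""

    a_q: float
    b_q: float
    sd_a_q: float
    sd_b_q: float
    c_lin: float
    sd_c_lin: float
    aic_quadratic: float
    aic_linear: float
    r2_quadratic: float
    r2_linear: float
    n_points: int

    @property
    def preferred(self) -> str:
        return "quadratic" if self.aic_quadratic < self.aic_linear else "linear"

    @property
    def delta_aic(self) -> float:
        """AIC(quadratic) - AIC(linear); negative favours the quadratic."""
        return self.aic_quadratic - self.aic_linear


# ---------------------------------------------------------------------------
# Normalization and point extraction
# ---------------------------------------------------------------------------

def _value_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in ("intake", "fat", "weight") if c in df.columns]


def normalize_to_control(exp: FeedingExperiment) -> FeedingExperiment:
    """Interpolate all series to an integer-day grid and divide by the control.

    Linear interpolation provides the common daily timescale; element-wise
    division by the interpolated control series turns every quantity into a
    fold change, cancelling shared growth trends (the control becomes
    identically 1).  The control must cover the full day range of every
    group; a gap raises an error naming it.
    """
    if exp.normalized:
        return exp
    df = exp.data
    cols = _value_columns(df)
    ctrl = df[df["group"] == exp.control_group].sort_values("day")
    lo_all = df["day"].min()
    hi_all = df["day"].max()
    c_lo, c_hi = ctrl["day"].min(), ctrl["day"].max()
    if c_lo > lo_all or c_hi < hi_all:
        raise ValueError(
            f"control series covers days [{c_lo:g}, {c_hi:g}] but groups span "
            f"[{lo_all:g}, {hi_all:g}]; cannot normalize outside the overlap"
        )
    out_rows = []
    for g in exp.groups:
        sub = df[df["group"] == g].sort_values("day")
        days = np.arange(math.ceil(sub["day"].min()), math.floor(sub["day"].max()) + 1)
        rec = {"group": g, "day": days}
        for col in cols:
            own = np.interp(days, sub["day"].to_numpy(), sub[col].to_numpy(dtype=float))
            ref = np.interp(days, ctrl["day"].to_numpy(), ctrl[col].to_numpy(dtype=float))
            if np.any(ref <= 0):
                raise ValueError(f"control column {col!r} is non-positive on the grid")
            rec[col] = own / ref
        out_rows.append(pd.DataFrame(rec))
    norm = pd.concat(out_rows, ignore_index=True)
    return replace(exp, data=norm, normalized=True)


def extract_phase_points(norm_exp: FeedingExperiment) -> PhasePortraitData:
    """Extract diet and appetite points from a normalized experiment.

    Diet point per group: the phase-mean relative intake over the controlled
    window (tube feeding was constant, so the mean is the controlled level)
    paired with the relative fat on the window's final day.  Appetite points:
    one (relative fat, relative intake) pair per group per recovery day.
    """
    if not norm_exp.normalized:
        norm_exp = normalize_to_control(norm_exp)
    df = norm_exp.data
    fat_col = "fat" if "fat" in df.columns else "weight"
    c0, c1 = norm_exp.controlled_window
    r0, r1 = norm_exp.recovery_window
    diet_rows, app_rows = [], []
    for g in norm_exp.groups:
        sub = df[df["group"] == g]
        ctrl_phase = sub[(sub["day"] >= c0) & (sub["day"] <= c1)]
        if ctrl_phase.empty:
            raise ValueError(f"group {g!r} has no samples in the controlled window")
        end_day = ctrl_phase["day"].max()
        diet_rows.append({
            "group": g,
            "u": float(ctrl_phase["intake"].mean()),
            "F": float(ctrl_phase.loc[ctrl_phase["day"] == end_day, fat_col].iloc[0]),
        })
        rec_phase = sub[(sub["day"] >= r0) & (sub["day"] <= r1)]
        if rec_phase.empty:
            raise ValueError(f"group {g!r} has no samples in the recovery window")
        for _, row in rec_phase.iterrows():
            app_rows.append({"group": g, "day": float(row["day"]),
                             "F": float(row[fat_col]), "u": float(row["intake"])})
    return PhasePortraitData(diet_points=pd.DataFrame(diet_rows),
                             appetite_points=pd.DataFrame(app_rows))


# ---------------------------------------------------------------------------
# Line fits
# ---------------------------------------------------------------------------

def _as_points(points, xcol: str, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, PhasePortraitData):
        raise TypeError("pass .diet_points or .appetite_points, not the container")
    if isinstance(points, pd.DataFrame):
        return points[xcol].to_numpy(dtype=float), points[ycol].to_numpy(dtype=float)
    arr = np.asarray(points, dtype=float)
    return arr[:, 0], arr[:, 1]


def fit_diet_line(points) -> DietLineFit:
    """Least-squares diet line F = a*u - b (F regressed on u).

    ``points``: DataFrame with columns u, F or an (N, 2) array of (u, F).
    Parameter SDs come from the residual covariance when there are at least
    3 points (with 2 the line interpolates exactly and no error estimate is
    possible -- flagged by ``sds_available``).
    """
    u, F = _as_points(points, "u", "F")
    if u.size < 2:
        raise ValueError("diet-line fit needs at least 2 points")
    if np.ptp(u) == 0:
        raise ValueError("degenerate diet points: all intakes equal")
    X = np.column_stack([u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(X, F, rcond=None)
    a, intercept = coef
    resid = F - X @ coef
    if u.size >= 3:
        dof = u.size - 2
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        sd_a, sd_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    else:
        sd_a = sd_b = None
    return DietLineFit(a=float(a), b=float(-intercept), sd_a=sd_a, sd_b=sd_b,
                       residuals=resid, n_points=int(u.size))


def appetite_model(u, c, umax, n):
    """Appetite line in fold-change form: F = (c/u) * (umax/u - 1)**(1/n)."""
    u = np.asarray(u, dtype=float)
    ratio = np.maximum(umax / u - 1.0, 0.0)
    return c / u * ratio ** (1.0 / n)


def fit_appetite_line(points, n_starts: tuple[float, ...] = (2.0, 5.0, 10.0, 20.0),
                      umax_bound_pad: float = 1e-6) -> AppetiteLineFit:
    """Nonlinear least squares for the appetite line with multi-start in n.

    Residuals are taken in fat units.  Bounds: c > 0, umax above the largest
    observed intake, n >= 1.  Each Hill-steepness start is tried and the
    converged solution with the lowest residual sum of squares is kept; if
    no start converges the per-start diagnostics are raised.
    """
    u, F = _as_points(points, "u", "F")
    if u.size < 4:
        raise ValueError("appetite-line fit needs at least 4 points")
    if np.any(u <= 0) or np.any(F < 0):
        raise ValueError("appetite points must have positive intake and non-negative fat")
    umax_lo = float(u.max()) * (1.0 + umax_bound_pad)
    bounds = ([1e-10, umax_lo, 1.0], [np.inf, np.inf, 1e4])
    c0 = float(np.median(F * u))
    best = None
    diagnostics = []
    converged = 0
    for n0 in n_starts:
        # Profile stage: (c, umax) at fixed Hill steepness.  The (umax, n)
        # pair trades off along a near-flat ridge when the data stop short of
        # the satiety cap, so a free 3-parameter start is easily lost; the
        # conditioned 2-parameter fit gives each steepness its best footing.
        try:
            prof, _ = curve_fit(lambda uu, c, um: appetite_model(uu, c, um, n0),
                                u, F, p0=[max(c0, 1e-6),
                                          max(1.25 * float(u.max()), umax_lo * 1.001)],
                                bounds=([1e-10, umax_lo], [np.inf, np.inf]),
                                maxfev=20000, method="trf")
            p0 = [prof[0], prof[1], n0]
        except Exception as exc:  # noqa: BLE001 - fall back to a raw start
            diagnostics.append(f"profile n0={n0:g}: {exc}")
            p0 = [max(c0, 1e-6), max(1.25 * float(u.max()), umax_lo * 1.001), n0]
        try:
            popt, pcov = curve_fit(appetite_model, u, F, p0=p0, bounds=bounds,
                                   maxfev=20000, method="trf")
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append(f"n0={n0:g}: {exc}")
            continue
        converged += 1
        rss = float(np.sum((F - appetite_model(u, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise RuntimeError("appetite-line fit failed from every start: " + " | ".join(diagnostics))
    _, popt, pcov = best
    sds = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = F - appetite_model(u, *popt)
    return AppetiteLineFit(c=float(popt[0]), umax=float(popt[1]), n=float(popt[2]),
                           sd_c=float(sds[0]), sd_umax=float(sds[1]), sd_n=float(sds[2]),
                           residuals=resid, n_points=int(u.size),
                           n_starts_converged=converged)


def fit_phase_portrait(data: PhasePortraitData) -> tuple[DietLineFit, AppetiteLineFit]:
    """Fit both lines of a normalized phase portrait."""
    return fit_diet_line(data.diet_points), fit_appetite_line(data.appetite_points)


def _aic_rss(rss: float, n: int, k: int) -> float:
    # Gaussian-likelihood AIC without the additive constant; only differences
    # between models fitted to the same data are meaningful.
    return n * math.log(rss / n) + 2 * k


def fit_leptin_fat(points) -> LeptinFatFit:
    """Fit L = a_q*F^2 + b_q*F vs L = c*F to a leptin-fat population scatter.

    ``points``: DataFrame with columns fat (or F) and leptin (or L), or an
    (N, 2) array of (F, L).  Both models are no-intercept least squares;
    they are compared by AIC and by the squared Pearson correlation between
    fitted and observed leptin.  Requires at least 5 points with F > 0.
    """
    if isinstance(points, pd.DataFrame):
        fcol = "fat" if "fat" in points.columns else "F"
        lcol = "leptin" if "leptin" in points.columns else "L"
        F = points[fcol].to_numpy(dtype=float)
        L = points[lcol].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        F, L = arr[:, 0], arr[:, 1]
    if F.size < 5:
        raise ValueError("leptin-fat fit needs at least 5 points")
    if np.any(F <= 0):
        raise ValueError("fat values must be strictly positive")
    N = F.size

    Xq = np.column_stack([F ** 2, F])
    coef_q, *_ = np.linalg.lstsq(Xq, L, rcond=None)
    fit_q = Xq @ coef_q
    rss_q = float(np.sum((L - fit_q) ** 2))
    cov_q = rss_q / (N - 2) * np.linalg.inv(Xq.T @ Xq)

    Xl = F[:, None]
    coef_l, *_ = np.linalg.lstsq(Xl, L, rcond=None)
    fit_l = Xl @ coef_l
    rss_l = float(np.sum((L - fit_l) ** 2))
    var_c = rss_l / (N - 1) / float(F @ F)

    r2_q = float(stats.pearsonr(fit_q, L).statistic ** 2)
    r2_l = float(stats.pearsonr(fit_l.ravel(), L).statistic ** 2)
    return LeptinFatFit(
        a_q=float(coef_q[0]), b_q=float(coef_q[1]),
        sd_a_q=float(np.sqrt(cov_q[0, 0])), sd_b_q=float(np.sqrt(cov_q[1, 1])),
        c_lin=float(coef_l[0]), sd_c_lin=float(np.sqrt(var_c)),
        aic_quadratic=_aic_rss(rss_q, N, 2), aic_linear=_aic_rss(rss_l, N, 1),
        r2_quadratic=r2_q, r2_linear=r2_l, n_points=int(N),
    )
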