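"""Diet line, appetite line, leptin nullclines, and the operating point.

The model couples fat mass ``F``, daily food intake ``u`` and circulating
leptin ``L``:

.. math::

    dF/dt &= a_F u - \\gamma_E - \\gamma_F F \\\\
    dL/dt &= a_L F u - \\gamma_L L \\\\
    u &= u_{max} / (1 + (L/K_L)^n)

Setting ``dF/dt = 0`` at a fixed, controlled intake gives the *diet line*
(steady-state fat rises linearly with intake).  Eliminating leptin at its
quasi-steady state from the intake rule gives the *appetite line*
(ad-libitum intake falls with fat).  Their intersection is the *operating
point*: the steady-state fat level that elicits exactly the intake needed to
maintain it.

Two regimes exist in the infinitely steep (``n -> inf``) limit:

* **above-critical** -- steady-state fat exceeds the critical fat level
  ``Fc = KL*gammaL/(aL*umax)``; leptin settles exactly at ``KL`` and intake
  varies inversely with fat.
* **satiety-capped** -- leptin resistance ``KL`` exceeds ``Kcrit``, intake is
  pinned at ``umax``, and fat is set by the diet line alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .parameters import ModelParameters

__all__ = [
    "OperatingPoint",
    "diet_line_intake",
    "inverse_diet_line_fat",
    "appetite_line_fat",
    "appetite_intake",
    "critical_fat",
    "kcrit",
    "solve_operating_point",
    "leptin_qss",
    "leptin_line",
    "fat_line",
    "fat_line_points",
    "hill_intake",
]

REGIME_ABOVE_CRITICAL = "above-critical"
REGIME_SATIETY_CAPPED = "satiety-capped"


@dataclass(frozen=True)
class OperatingPoint:
    """Steady state of the fat-leptin feedback loop.

    ``regime`` is meaningful in the n->inf limit: ``"satiety-capped"`` iff
    ``KL >= Kcrit`` iff ``Fst <= Fc``.  The boundary ``KL == Kcrit`` is
    assigned to the above-critical regime (closed-interval convention), where
    the two closed forms agree by continuity.
    """

    Fst: float
    ust: float
    Lst: float
    Fc: float
    Kcrit: float
    regime: str


def _as_float_or_array(x):
    arr = np.asarray(x, dtype=float)
    return arr


def diet_line_intake(F, p: ModelParameters):
    """Controlled intake that maintains fat mass ``F`` at steady state.

    The diet line read as intake-at-fat: ``u = (gammaF*F + gammaE)/aF``,
    strictly increasing in F.  Negative fat is rejected.
    """
    F = _as_float_or_array(F)
    if np.any(F < 0):
        raise ValueError("fat mass must be non-negative on the diet line")
    u = (p.gammaF * F + p.gammaE) / p.aF
    return u if u.ndim else float(u)


def inverse_diet_line_fat(u, p: ModelParameters):
    """Steady-state fat maintained by a controlled intake ``u`` (inverse diet line)."""
    u = _as_float_or_array(u)
    F = (p.aF * u - p.gammaE) / p.gammaF
    return F if F.ndim else float(F)


def hill_intake(L, p: ModelParameters, n: float | None = None):
    """Ad-libitum intake at leptin level ``L``: ``umax / (1 + (L/KL)**n)``.

    Overflow-safe for large ``n``; ``n=inf`` gives the hard threshold at
    ``L = KL`` (with the midpoint value ``umax/2`` exactly at the threshold).
    """
    n = p.n if n is None else n
    L = _as_float_or_array(L)
    if np.any(L < 0):
        raise ValueError("leptin concentration must be non-negative")
    if math.isinf(n):
        u = np.where(L < p.KL, p.umax, np.where(L > p.KL, 0.0, 0.5 * p.umax))
    else:
        with np.errstate(divide="ignore"):
            s = n * np.log(np.maximum(L, 0.0) / p.KL)
        u = p.umax * expit(-s)
    return u if u.ndim else float(u)


def critical_fat(p: ModelParameters) -> float:
    """Critical fat level ``Fc = KL*gammaL/(aL*umax)``.

    Below Fc (in the n->inf limit) intake locks at its maximal satiety value
    umax -- the anti-starvation response.  Fc is proportional to KL, so
    leptin-resistant individuals mount the response at higher fat.
    """
    return p.KL * p.gammaL / (p.aL * p.umax)


def kcrit(p: ModelParameters) -> float:
    """Leptin-resistance threshold at which the satiety-capped regime begins.

    Defined by the equality of the critical fat level with the diet-line fat
    at ``u = umax``; solving ``KL*gammaL/(aL*umax) = (aF*umax - gammaE)/gammaF``
    for KL gives ``Kcrit = aL*umax*(aF*umax - gammaE)/(gammaL*gammaF)``.
    """
    p.require_feasible()
    return p.aL * p.umax * (p.aF * p.umax - p.gammaE) / (p.gammaL * p.gammaF)


def appetite_line_fat(u, p: ModelParameters, n: float | None = None):
    """Fat level at which ad-libitum intake equals ``u`` (appetite line, finite n).

    ``F = (gammaL*KL/aL) * (1/u) * (umax/u - 1)**(1/n)``; strictly decreasing
    in ``u`` on the open domain ``0 < u < umax``.
    """
    n = p.n if n is None else n
    if math.isinf(n):
        raise ValueError("appetite_line_fat requires finite n; use appetite_intake for the n->inf limit")
    u = _as_float_or_array(u)
    if np.any(u <= 0) or np.any(u >= p.umax):
        raise ValueError(f"intake must lie strictly inside (0, umax={p.umax:g})")
    F = (p.gammaL * p.KL / p.aL) / u * (p.umax / u - 1.0) ** (1.0 / n)
    return F if F.ndim else float(F)


def _appetite_intake_scalar(F: float, p: ModelParameters, n: float) -> float:
    if F < 0:
        raise ValueError("fat mass must be non-negative")
    if math.isinf(n):
        Fc = critical_fat(p)
        if F <= Fc:
            return p.umax
        return Fc * p.umax / F
    if F == 0.0:
        return p.umax
    # u solves u = umax / (1 + ((aL/(gammaL*KL)) * F * u)**n); the map is
    # monotone so the fixed point is the unique root of
    # g(u) = u * (1 + (k*F*u)**n) - umax on (0, umax].
    k = p.aL / (p.gammaL * p.KL)

    def g(u: float) -> float:
        with np.errstate(over="ignore"):
            t = n * math.log(k * F * u) if u > 0 else -math.inf
            if t > 700.0:
                return math.inf
            return u * (1.0 + math.exp(t)) - p.umax

    lo = 1e-12 * p.umax
    hi = p.umax
    glo, ghi = g(lo), g(hi)
    if glo > 0:
        # pathological: even vanishing intake saturates leptin; report bracket
        raise RuntimeError(
            f"appetite fixed point not bracketed: g({lo:g})={glo:g}, g({hi:g})={ghi:g}"
        )
    if ghi <= 0:
        return p.umax
    try:
        return brentq(g, lo, hi, xtol=1e-14, rtol=1e-12, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"appetite fixed-point root finding failed on bracket ({lo:g}, {hi:g}): {exc}"
        ) from exc


def appetite_intake(F, p: ModelParameters, n: float | None = None):
    """Ad-libitum intake at fat level ``F`` (the appetite line as u(F)).

    In the n->inf limit: ``u = umax`` for ``F <= Fc`` and ``u = Fc*umax/F``
    above.  At finite n the intake solves the leptin quasi-steady-state fixed
    point by bracketed root-finding; continuous and non-increasing in F.
    """
    n = p.n if n is None else n
    F = _as_float_or_array(F)
    if F.ndim == 0:
        return _appetite_intake_scalar(float(F), p, n)
    return np.array([_appetite_intake_scalar(float(f), p, n) for f in F.ravel()]).reshape(F.shape)


def leptin_qss(F, u, p: ModelParameters):
    """Quasi-steady-state leptin ``L = (aL/gammaL) * F * u`` (bilinear in F, u)."""
    F = _as_float_or_array(F)
    u = _as_float_or_array(u)
    if np.any(F < 0) or np.any(u < 0):
        raise ValueError("fat and intake must be non-negative")
    L = (p.aL / p.gammaL) * F * u
    return L if L.ndim else float(L)


def leptin_line(F, p: ModelParameters):
    """Steady-state leptin at fat ``F`` along the diet line (quadratic in F).

    ``L = (aL/(gammaL*aF)) * F * (gammaF*F + gammaE)`` -- identical to
    ``leptin_qss(F, diet_line_intake(F))``.  The quadratic term exists because
    leptin production scales with recent food intake as well as fat; without
    that dependence the relation would be linear.
    """
    F = _as_float_or_array(F)
    if np.any(F < 0):
        raise ValueError("fat mass must be non-negative")
    L = (p.aL / (p.gammaL * p.aF)) * F * (p.gammaF * F + p.gammaE)
    return L if L.ndim else float(L)


def fat_line(L, p: ModelParameters, n: float | None = None):
    """Steady-state fat when leptin is clamped at ``L`` (the fat nullcline).

    Finite n: ``F = (aF/gammaF)*umax/(1 + (L/KL)**n) - gammaE/gammaF``.
    n->inf: a piecewise constant with plateaus ``(aF*umax - gammaE)/gammaF``
    (L < KL) and ``-gammaE/gammaF`` (L > KL).  Negative values are returned
    as-is; they flag a state of diminished fat stores in which lean mass
    would be catabolized (fat itself cannot be negative).  Use
    :func:`fat_line_points` for an explicit flag column.
    """
    n = p.n if n is None else n
    L = _as_float_or_array(L)
    if np.any(L < 0):
        raise ValueError("leptin concentration must be non-negative")
    F = (p.aF / p.gammaF) * hill_intake(L, p, n=n) - p.gammaE / p.gammaF
    return F if np.ndim(F) else float(F)


def fat_line_points(L_values, p: ModelParameters, n: float | None = None):
    """Tabulate the fat line with an explicit diminished-stores flag.

    Returns a pandas DataFrame with columns ``L``, ``F``, ``diminished``
    (True where the formal solution is negative).
    """
    import pandas as pd

    L_values = np.atleast_1d(np.asarray(L_values, dtype=float))
    F = np.atleast_1d(fat_line(L_values, p, n=n))
    return pd.DataFrame({"L": L_values, "F": F, "diminished": F < 0})


def _numeric_intersection(p: ModelParameters, n: float) -> float:
    """Bracketed root of diet_line_intake(F) - appetite_intake(F); independent of
    the closed forms, used as a built-in cross-check."""
    p.require_feasible()

    def diff(F: float) -> float:
        return diet_line_intake(F, p) - _appetite_intake_scalar(F, p, n)

    lo = 0.0
    hi = (p.aF * p.umax - p.gammaE) / p.gammaF  # fat where the diet line reaches umax
    dlo = diff(lo)
    if dlo >= 0:
        raise RuntimeError("no positive intersection: diet line starts above the appetite line")
    dhi = diff(hi)
    if dhi < 0:
        # finite-n appetite can exceed the diet line slightly beyond hi; expand
        while diff(hi) < 0:
            hi *= 1.5
            if hi > 1e6:
                raise RuntimeError("no intersection found while expanding bracket")
    return brentq(diff, lo, hi, xtol=1e-300, rtol=1e-13, maxiter=200)


def solve_operating_point(p: ModelParameters, n: float | None = None,
                          cross_validate: bool = True) -> OperatingPoint:
    """Solve for the operating point (steady-state fat, intake, leptin).

    n->inf uses the closed forms of the two regimes; finite n intersects the
    diet line with the fixed-point appetite line numerically.  The closed-form
    branch is cross-validated against an independent bracketed numeric
    intersection to a relative 1e-8 unless ``cross_validate=False``.
    """
    n = p.n if n is None else n
    p.require_feasible()
    Fc = critical_fat(p)
    Kc = kcrit(p)

    if math.isinf(n):
        if p.KL >= Kc:
            regime = REGIME_SATIETY_CAPPED if p.KL > Kc else REGIME_ABOVE_CRITICAL
            ust = p.umax
            Fst = (p.aF * p.umax - p.gammaE) / p.gammaF
            Lst = (p.aL / p.gammaL) * Fst * p.umax
        else:
            regime = REGIME_ABOVE_CRITICAL
            # diet line meets u = Fc*umax/F = KL*gammaL/(aL*F):
            # gammaF*F^2 + gammaE*F - aF*KL*gammaL/aL = 0, positive root.
            c0 = p.aF * p.KL * p.gammaL / p.aL
            disc = p.gammaE * p.gammaE + 4.0 * p.gammaF * c0
            Fst = (-p.gammaE + math.sqrt(disc)) / (2.0 * p.gammaF)
            ust = p.KL * p.gammaL / (p.aL * Fst)
            Lst = p.KL
        if cross_validate:
            F_num = _numeric_intersection(p, n)
            if not math.isclose(F_num, Fst, rel_tol=1e-8):
                raise RuntimeError(
                    f"closed-form operating point Fst={Fst!r} disagrees with the "
                    f"numeric intersection {F_num!r}"
                )
    else:
        Fst = _numeric_intersection(p, n)
        ust = diet_line_intake(Fst, p)
        Lst = leptin_qss(Fst, ust, p)
        regime = REGIME_SATIETY_CAPPED if p.KL > Kc else REGIME_ABOVE_CRITICAL
    return OperatingPoint(Fst=float(Fst), ust=float(ust), Lst=float(Lst),
                          Fc=float(Fc), Kcrit=float(Kc), regime=regime)
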