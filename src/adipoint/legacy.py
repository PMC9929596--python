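"""Diet and appetite lines derived from two earlier leptin-based models.

The operating-point framework only needs a rising diet curve (steady-state
fat at a controlled intake) and a falling appetite curve (ad-libitum intake
at a given fat).  Both can be extracted from richer published models, which
demonstrates that the framework is not tied to one particular mechanism:

* **Tam et al. (2009)** -- leptin produced by fat and cleared renally,
  saturable plus linear transport into the brain, Michaelis-Menten
  suppression of intake and leptin-amplified energy expenditure.  The
  variant analyzed here has no explicit set-point controller.
* **Jacquier et al. (2015)** -- energy balance with a body-composition
  function linking fat-free mass to fat, leptin produced proportionally to
  fat, and a Hill-type receptor response inhibiting intake.  The variant
  analyzed here holds the leptin-receptor density fixed.

Neither model makes leptin production depend on recent food intake, so
neither reproduces the quadratic leptin-fat population curve; they do both
yield the two lines and an operating point at their crossing.

The numeric parameter values shipped with this module are *synthetic
representative sets* (see ``presets/tam2009_synthetic.yaml`` and
``presets/jacquier2015_synthetic.yaml``): they are chosen to exhibit the
structural behaviour (rising/falling curves, a unique crossing) and are not
the calibrated values of the original publications, which should be taken
from those papers' parameter tables when quantitative work is intended.
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import core
from .parameters import ModelParameters

__all__ = [
    "TamParameters",
    "JacquierParameters",
    "load_tam_parameters",
    "load_jacquier_parameters",
    "tam_brain_leptin",
    "tam_diet_intake",
    "tam_diet_intake_low_fat",
    "tam_diet_intake_high_fat",
    "tam_appetite_intake",
    "tam_lines",
    "jacquier_ffm",
    "jacquier_diet_intake",
    "jacquier_appetite_intake",
    "jacquier_lines",
    "compare_operating_points",
]

_PRESET_DIR = os.path.join(os.path.dirname(__file__), "presets")


@dataclass(frozen=True)
class TamParameters:
    """Constants of the Tam et al. (2009) energy-metabolism model.

    ``alphaL`` groups leptin synthesis per unit fat over blood volume and
    ``gammaL_t`` the renal clearance rate; ``k1``-``k3`` set saturable and
    linear brain transport, ``k4``/``k5`` maximal intake and its brain-leptin
    half-effect, ``k6``-``k8`` the expenditure rate and its leptin
    amplification; ``rho_food`` and ``rho_F`` are energy densities; ``FFM``
    is the (constant) fat-free mass.  All strictly positive.
    """

    alphaL: float = 1.0
    gammaL_t: float = 1.0
    k1: float = 2.0
    k2: float = 1.0
    k3: float = 0.1
    k4: float = 5.0
    k5: float = 1.0
    k6: float = 0.12
    k7: float = 0.8
    k8: float = 1.0
    rho_food: float = 3.0
    rho_F: float = 9.0
    FFM: float = 20.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"Tam parameter {name!r} must be positive, got {value!r}")


@dataclass(frozen=True)
class JacquierParameters:
    """Constants of the Jacquier et al. (2015) leptin-resistance model.

    ``rho_FFM``/``rho_F`` caloric densities; ``gammaOmega``, ``alpha``,
    ``kappa``, ``C`` the body-composition function and its integration
    constant; ``eta``/``xi`` expenditure rate and basal term; ``cal_density``
    the food's caloric density (the source's own "gamma_E", renamed to avoid
    clashing with the operating-point model's energy-cost rate); ``gammaL_j``
    and ``deltaL`` leptin production/degradation; ``phiR`` the maximal
    receptor response (the product of the response amplitude and the fixed
    receptor density); ``theta``/``n_h`` the Hill half-point and exponent;
    ``gamma_u``/``delta_u`` intake production/decay.
    """

    rho_FFM: float = 1.8
    rho_F: float = 9.4
    gammaOmega: float = 0.2
    alpha: float = 1.0
    kappa: float = 0.05
    C: float = 2.0
    eta: float = 0.05
    xi: float = 5.0
    cal_density: float = 3.0
    gammaL_j: float = 1.0
    deltaL: float = 1.0
    phiR: float = 2.0
    theta: float = 10.0
    n_h: float = 2.0
    gamma_u: float = 10.0
    delta_u: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"Jacquier parameter {name!r} must be positive, got {value!r}")


def _load_yaml_params(path: str, cls):
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return cls(**data)


def load_tam_parameters(path: str | None = None) -> TamParameters:
    """Load Tam-model parameters from YAML (default: the synthetic preset)."""
    return _load_yaml_params(path or os.path.join(_PRESET_DIR, "tam2009_synthetic.yaml"),
                             TamParameters)


def load_jacquier_parameters(path: str | None = None) -> JacquierParameters:
    """Load Jacquier-model parameters from YAML (default: the synthetic preset)."""
    return _load_yaml_params(path or os.path.join(_PRESET_DIR, "jacquier2015_synthetic.yaml"),
                             JacquierParameters)


# ---------------------------------------------------------------------------
# Tam et al. (2009)
# ---------------------------------------------------------------------------

def tam_brain_leptin(F, tp: TamParameters):
    """Brain leptin at fat F with plasma leptin at quasi-steady state.

    Plasma leptin settles at ``alphaL*F/gammaL_t``; transport into the brain
    has a saturable component ``Lp*k1/(Lp + k2)`` plus linear diffusion
    ``Lp*k3``.
    """
    F = np.asarray(F, dtype=float)
    Lp = tp.alphaL * F / tp.gammaL_t
    Lb = Lp * tp.k1 / (Lp + tp.k2) + Lp * tp.k3
    return Lb if Lb.ndim else float(Lb)


def tam_diet_intake(F, tp: TamParameters):
    """Tam diet curve: intake that balances expenditure at fat F.

    ``u = k6*(F + FFM) * (Lb*(1 + k7) + k8) / (rho_food * (Lb + k8))`` with
    brain leptin from :func:`tam_brain_leptin`; rises with F and sits between
    the low-fat and high-fat linear limits.
    """
    F = np.asarray(F, dtype=float)
    Lb = np.asarray(tam_brain_leptin(F, tp))
    u = tp.k6 * (F + tp.FFM) * (Lb * (1.0 + tp.k7) + tp.k8) / (tp.rho_food * (Lb + tp.k8))
    return u if u.ndim else float(u)


def tam_diet_intake_low_fat(F, tp: TamParameters):
    """Low-fat linear limit of the Tam diet curve: ``u = k6*(F + FFM)/rho_food``."""
    F = np.asarray(F, dtype=float)
    u = tp.k6 * (F + tp.FFM) / tp.rho_food
    return u if u.ndim else float(u)


def tam_diet_intake_high_fat(F, tp: TamParameters):
    """High-fat linear limit: ``u = k6*(F + FFM)*(1 + k7)/rho_food``."""
    F = np.asarray(F, dtype=float)
    u = tp.k6 * (F + tp.FFM) * (1.0 + tp.k7) / tp.rho_food
    return u if u.ndim else float(u)


def tam_appetite_intake(F, tp: TamParameters):
    """Tam appetite curve: ``u = k4*k5/(Lb + k5)``; equals k4 at zero fat."""
    F = np.asarray(F, dtype=float)
    Lb = np.asarray(tam_brain_leptin(F, tp))
    u = tp.k4 * tp.k5 / (Lb + tp.k5)
    return u if u.ndim else float(u)


def tam_lines(F_grid, tp: TamParameters | None = None) -> pd.DataFrame:
    """Tabulate the Tam diet and appetite curves on a fat grid.

    Returns a DataFrame with columns F, u_diet, u_appetite.
    """
    tp = tp or TamParameters()
    F = np.asarray(F_grid, dtype=float)
    if np.any(F < 0):
        raise ValueError("fat grid must be non-negative")
    return pd.DataFrame({"F": F, "u_diet": tam_diet_intake(F, tp),
                         "u_appetite": tam_appetite_intake(F, tp)})


# ---------------------------------------------------------------------------
# Jacquier et al. (2015)
# ---------------------------------------------------------------------------

def jacquier_ffm(F, jp: JacquierParameters):
    """Fat-free mass from fat via the body-composition function:
    ``FFM = gammaOmega*(kappa*F + alpha*exp(kappa*F))/kappa + C``."""
    F = np.asarray(F, dtype=float)
    ffm = jp.gammaOmega * (jp.kappa * F + jp.alpha * np.exp(jp.kappa * F)) / jp.kappa + jp.C
    return ffm if ffm.ndim else float(ffm)


def jacquier_diet_intake(F, jp: JacquierParameters):
    """Jacquier diet curve: intake holding fat steady at F.

    ``u = eta*(gammaOmega*rho_FFM*alpha*e^(kappa F)
    + kappa*(C*rho_FFM + F*gammaOmega*rho_FFM + F*rho_F + xi)) /
    (cal_density*kappa)``; linear in F when alpha = 0.
    """
    F = np.asarray(F, dtype=float)
    num = (jp.gammaOmega * jp.rho_FFM * jp.alpha * np.exp(jp.kappa * F)
           + jp.kappa * (jp.C * jp.rho_FFM + F * jp.gammaOmega * jp.rho_FFM
                         + F * jp.rho_F + jp.xi))
    u = jp.eta * num / (jp.cal_density * jp.kappa)
    return u if u.ndim else float(u)


def jacquier_appetite_intake(F, jp: JacquierParameters):
    """Jacquier appetite curve under leptin quasi-steady state.

    ``u = gamma_u*(F^n*gL^n + dL^n*theta^n) /
    (delta_u*(F^n*gL^n*(1 + phiR) + dL^n*theta^n))``; equals
    ``gamma_u/delta_u`` at zero fat and decreases toward
    ``gamma_u/(delta_u*(1 + phiR))``.
    """
    F = np.asarray(F, dtype=float)
    a = (F * jp.gammaL_j) ** jp.n_h
    b = (jp.deltaL * jp.theta) ** jp.n_h
    u = jp.gamma_u * (a + b) / (jp.delta_u * (a * jp.phiR + a + b))
    return u if u.ndim else float(u)


def jacquier_lines(F_grid, jp: JacquierParameters | None = None) -> pd.DataFrame:
    """Tabulate the Jacquier diet and appetite curves on a fat grid."""
    jp = jp or JacquierParameters()
    F = np.asarray(F_grid, dtype=float)
    if np.any(F < 0):
        raise ValueError("fat grid must be non-negative")
    return pd.DataFrame({"F": F, "u_diet": jacquier_diet_intake(F, jp),
                         "u_appetite": jacquier_appetite_intake(F, jp)})


# ---------------------------------------------------------------------------
# Operating points across models
# ---------------------------------------------------------------------------

def compare_operating_points(model: str, params=None, F_grid=None,
                             n: float | None = None) -> tuple[float, float]:
    """Locate the diet/appetite crossing for one of the three models.

    ``model`` is ``"operating-point"``, ``"tam"`` or ``"jacquier"``.  Returns
    ``(F, u)`` at the intersection, found by bracketed root-finding on the
    curve difference over ``F_grid`` (default grids suit the shipped
    parameter sets).  Raises if the difference never changes sign on the
    grid.
    """
    if model == "operating-point":
        p = params or ModelParameters()
        op = core.solve_operating_point(p, n=n)
        return op.Fst, op.ust
    if model == "tam":
        tp = params or TamParameters()
        grid = np.asarray(F_grid if F_grid is not None else np.linspace(0.01, 60.0, 400))
        diff = lambda F: tam_diet_intake(F, tp) - tam_appetite_intake(F, tp)  # noqa: E731
    elif model == "jacquier":
        jp = params or JacquierParameters()
        grid = np.asarray(F_grid if F_grid is not None else np.linspace(0.01, 60.0, 400))
        diff = lambda F: jacquier_diet_intake(F, jp) - jacquier_appetite_intake(F, jp)  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}")
    vals = np.array([diff(F) for F in grid])
    sign_changes = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if len(sign_changes) == 0:
        raise RuntimeError(f"{model} curves do not cross on the grid "
                           f"[{grid[0]:g}, {grid[-1]:g}]")
    i = sign_changes[0]
    F_star = brentq(diff, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
    if model == "tam":
        return float(F_star), float(tam_diet_intake(F_star, params or TamParameters()))
    return float(F_star), float(jacquier_diet_intake(F_star, params or JacquierParameters()))
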