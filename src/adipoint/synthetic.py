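"""Synthetic datasets with the statistical structure the analyses assume.

Two generators cover the package's data-driven pipelines without any
downloads:

* :func:`generate_feeding_experiment` emulates the Harris-type rodent
  protocol -- groups tube-fed 40/100/160% of the control intake for 20 days
  and then returned to ad-libitum feeding -- by simulating the model with
  clamped intake followed by free dynamics, superimposing a shared
  multiplicative growth trend and lognormal measurement noise.
* :func:`generate_leptin_population` emulates a leptin-fat population
  scatter: one varied physiological parameter per individual (lognormal
  inter-individual variation, leptin resistance ``KL`` by default), each
  individual solved to its operating point, with lognormal measurement noise
  on leptin.  Because every operating point lies on the leptin nullcline,
  the noise-free scatter traces the quadratic
  ``L = (aL/(gammaL*aF)) * F * (gammaF*F + gammaE)`` exactly.

Two further helpers, :func:`harris_like_phase_portrait` and
:func:`considine_like_scatter`, are *synthetic stand-ins* for the digitized
Harris et al. (1986) refeeding phase portrait and the Considine et
al. (1996) human leptin-fat scatter: they draw points from line shapes with
coefficients at the published normalized-fit scale, for exercising the
fitting pipeline when the digitized data files are not at hand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, dynamics
from .fitting import FeedingExperiment, PhasePortraitData
from .parameters import ModelParameters, PhasePoint

__all__ = [
    "FeedingDesign",
    "PopulationDesign",
    "generate_feeding_experiment",
    "generate_leptin_population",
    "harris_like_phase_portrait",
    "considine_like_scatter",
    "HARRIS_LIKE_COEFFICIENTS",
    "CONSIDINE_LIKE_COEFFICIENTS",
]


@dataclass(frozen=True)
class FeedingDesign:
    """Design of a synthetic controlled-feeding experiment.

    Defaults mirror the rodent protocol: feeding fractions 40/100/160% of
    control, 20 days of controlled feeding, 30 days of ad-libitum recovery.
    ``growth_rate`` is a shared multiplicative trend per day on fat and
    weight (it cancels under control normalization); ``noise_sigma`` is the
    lognormal sigma applied to measured intake, fat and weight.
    """

    fractions: tuple[float, ...] = (0.4, 1.0, 1.6)
    controlled_days: int = 20
    recovery_days: int = 30
    growth_rate: float = 0.005
    noise_sigma: float = 0.05
    seed: int = 0
    lean_mass_multiple: float = 8.0  # lean mass as a multiple of steady-state fat
    sparse_fat_every: int | None = None  # emit fat every k days only (None = daily)
    # Model time units per protocol day.  The model's rates are expressed per
    # leptin-turnover time (~140 min), so a day spans 1440/140 of them; with
    # this value the 20-day controlled phase equilibrates fat to <1%, as the
    # diet-line construction assumes, and leptin is fast relative to a day.
    time_units_per_day: float = 1440.0 / 140.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("feeding fractions must be positive")
        if 1.0 not in self.fractions:
            raise ValueError("a control (fraction 1.0) group is required")
        if self.controlled_days < 1 or self.recovery_days < 1:
            raise ValueError("phase lengths must be positive integers")
        if self.noise_sigma < 0 or self.growth_rate < 0:
            raise ValueError("noise and growth parameters must be non-negative")


@dataclass(frozen=True)
class PopulationDesign:
    """Design of a synthetic leptin-fat population.

    ``varied``: the parameter drawn per individual (lognormally around its
    preset value); ``variation_sigma`` the lognormal sigma of that draw;
    ``noise_sigma`` the lognormal measurement noise on leptin.
    """

    n_individuals: int = 70
    varied: str = "KL"
    variation_sigma: float = 0.5
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 5:
            raise ValueError("population needs at least 5 individuals")
        if self.variation_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.varied not in ("aF", "gammaF", "gammaE", "aL", "gammaL", "KL", "umax"):
            raise ValueError(f"unknown varied parameter {self.varied!r}")


def _group_label(fraction: float) -> str:
    return f"{fraction * 100:g}%"


def generate_feeding_experiment(p: ModelParameters, design: FeedingDesign | None = None,
                                cfg: dynamics.SimulationConfig | None = None
                                ) -> FeedingExperiment:
    """Simulate a tube-feeding + recovery experiment and emit noisy daily data.

    Each group starts at the operating point, is clamped to
    ``fraction x control intake`` for the controlled phase (fat then follows
    the linear balance equation exactly), and eats ad libitum during
    recovery (full fat-leptin dynamics).  Daily intake is the within-day mean
    of the simulated intake, as a feeding experiment records.  The default
    recovery steepness is n=7.1, the value estimated from the rodent
    refeeding phase portrait.

    Output follows the feeding CSV schema (group, day, intake, fat, weight)
    with the design's growth trend and lognormal noise applied; the seed is
    recorded implicitly by determinism (same design -> identical output).
    """
    design = design or FeedingDesign()
    upd = design.time_units_per_day
    cfg = cfg or dynamics.SimulationConfig(n_dynamics=7.1,
                                           t_end=design.recovery_days * upd,
                                           dt_out=upd)
    rng = np.random.default_rng(design.seed)
    n_sim = cfg.n_dynamics if math.isinf(p.n) else p.n
    op = core.solve_operating_point(p, n=n_sim)
    u_control = op.ust
    lean = design.lean_mass_multiple * op.Fst
    T1, T2 = design.controlled_days, design.recovery_days

    frames = []
    for frac in design.fractions:
        u_clamp = frac * u_control
        clamped = dynamics.simulate_clamped_intake(p, op.Fst, u_clamp, T1 * upd, dt_out=upd)
        F_end = float(clamped.F[-1])
        rec_cfg = dynamics.SimulationConfig(n_dynamics=cfg.n_dynamics, t_end=T2 * upd,
                                            dt_out=upd, rel_tol=cfg.rel_tol,
                                            abs_tol=cfg.abs_tol, leptin_mode=cfg.leptin_mode)
        recovery = dynamics.simulate(p, PhasePoint(F=F_end, u=u_clamp), rec_cfg)
        rec_daily = dynamics.daily_intake(recovery, day_length=upd)

        days = np.arange(1, T1 + T2 + 1)
        intake = np.concatenate([np.full(T1, u_clamp), rec_daily["intake"].to_numpy()])
        fat = np.concatenate([clamped.F[1:T1 + 1], rec_daily["fat"].to_numpy()])
        trend = np.exp(design.growth_rate * days)
        weight = (fat + lean) * trend
        fat = fat * trend
        if design.noise_sigma > 0:
            intake = intake * np.exp(design.noise_sigma * rng.standard_normal(intake.size))
            fat = fat * np.exp(design.noise_sigma * rng.standard_normal(fat.size))
            weight = weight * np.exp(design.noise_sigma * rng.standard_normal(weight.size))
        frame = pd.DataFrame({"group": _group_label(frac), "day": days,
                              "intake": intake, "fat": fat, "weight": weight})
        if design.sparse_fat_every is not None:
            keep = (days % design.sparse_fat_every == 0) | (days == T1) | (days == days[-1])
            frame.loc[~keep, "fat"] = np.nan
            frame["fat"] = frame["fat"].interpolate(method="linear", limit_direction="both")
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    return FeedingExperiment(data=data, control_group=_group_label(1.0),
                             controlled_window=(1.0, float(T1)),
                             recovery_window=(float(T1 + 1), float(T1 + T2)))


def generate_leptin_population(p: ModelParameters, design: PopulationDesign | None = None
                               ) -> pd.DataFrame:
    """Draw a population, solve each operating point, return a (fat, leptin) scatter.

    Individuals whose parameter draw admits no positive-fat steady state are
    skipped; their count is reported in ``DataFrame.attrs['n_skipped']``.
    Columns: fat, leptin, plus the drawn parameter value for reference.
    """
    design = design or PopulationDesign()
    rng = np.random.default_rng(design.seed)
    base_value = getattr(p, design.varied)
    draws = base_value * np.exp(design.variation_sigma * rng.standard_normal(design.n_individuals))
    rows = []
    skipped = 0
    for value in draws:
        pi = p.with_(**{design.varied: float(value)})
        if not pi.feasible_positive_fat:
            skipped += 1
            continue
        op = core.solve_operating_point(pi)
        L = op.Lst
        if design.noise_sigma > 0:
            L = L * float(np.exp(design.noise_sigma * rng.standard_normal()))
        rows.append({"fat": op.Fst, "leptin": L, design.varied: float(value)})
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = skipped
    out.attrs["seed"] = design.seed
    return out


# ---------------------------------------------------------------------------
# Labelled synthetic stand-ins for the digitized literature datasets
# ---------------------------------------------------------------------------

#: Normalized-fit scale of the rodent refeeding phase portrait: diet line
#: F = a*u - b and appetite line F = (c/u)*(umax/u - 1)**(1/n).
HARRIS_LIKE_COEFFICIENTS = {"a": 1.56, "b": 0.49, "c": 1.0, "umax": 1.38, "n": 7.1}

#: Human population leptin-fat curve L = a_q*F^2 + b_q*F (fat in % body fat,
#: leptin in ng/ml).
CONSIDINE_LIKE_COEFFICIENTS = {"a_q": 0.016, "b_q": 0.062}


def harris_like_phase_portrait(seed: int = 0, n_appetite_points: int = 39,
                               noise_sigma: float = 0.02,
                               coefficients: dict | None = None) -> PhasePortraitData:
    """Synthetic stand-in for the digitized rodent refeeding phase portrait.

    Draws the three diet points exactly on the normalized diet line at the
    protocol's relative intakes (0.4, 1.0, 1.6) and ``n_appetite_points``
    recovery points on the appetite line over the intake range the recovery
    data cover, with small lognormal noise on fat.  This is a synthetic
    emulation of the Harris et al. (1986) digitized data -- use the real
    deposited CSVs instead whenever they are available.
    """
    coef = dict(HARRIS_LIKE_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    rng = np.random.default_rng(seed)
    u_diet = np.array([0.4, 1.0, 1.6])
    F_diet = coef["a"] * u_diet - coef["b"]
    diet = pd.DataFrame({"group": ["40%", "100%", "160%"], "u": u_diet, "F": F_diet})

    u_app = np.linspace(0.62, 1.30, n_appetite_points)
    from .fitting import appetite_model

    F_app = appetite_model(u_app, coef["c"], coef["umax"], coef["n"])
    F_app = F_app * np.exp(noise_sigma * rng.standard_normal(F_app.size))
    appetite = pd.DataFrame({"group": "recovery", "day": np.arange(1, n_appetite_points + 1,
                                                                   dtype=float),
                             "F": F_app, "u": u_app})
    return PhasePortraitData(diet_points=diet, appetite_points=appetite)


def considine_like_scatter(seed: int = 0, n_points: int = 70,
                           fat_range: tuple[float, float] = (8.0, 45.0),
                           noise_sigma: float = 0.25,
                           coefficients: dict | None = None) -> pd.DataFrame:
    """Synthetic stand-in for the digitized human leptin-fat population scatter.

    Fat (% body fat) is drawn uniformly over ``fat_range``; leptin follows
    the quadratic population curve with multiplicative lognormal scatter
    (serum leptin is positive and its dispersion grows with its level).
    This is a synthetic emulation of the Considine et al. (1996) digitized
    data -- use the real deposited CSV instead whenever it is available.
    """
    coef = dict(CONSIDINE_LIKE_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    rng = np.random.default_rng(seed)
    F = rng.uniform(*fat_range, size=n_points)
    L_mean = coef["a_q"] * F ** 2 + coef["b_q"] * F
    L = L_mean * np.exp(noise_sigma * rng.standard_normal(n_points))
    return pd.DataFrame({"fat": F, "leptin": L})
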