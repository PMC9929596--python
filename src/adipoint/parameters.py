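"""Model parameters, named presets, and parameter-file IO.

The operating-point model of body-fat regulation has seven rate/feedback
constants plus the Hill steepness of leptin's effect on intake:

==========  ===================================================================
``aF``      fat gained per unit food intake (fat-mass / intake-mass per time)
``gammaF``  fat self-maintenance cost rate (1/time)
``gammaE``  body energy cost excluding fat upkeep (fat-mass / time)
``aL``      leptin production coefficient (leptin / (fat * intake * time))
``gammaL``  leptin clearance rate (1/time)
``KL``      leptin half-effect concentration; rises with leptin resistance
``umax``    maximal "satiety" food intake (intake-mass / time)
``n``       Hill steepness of leptin's suppression of intake; ``math.inf``
            selects the infinitely steep limit used for closed-form analysis
==========  ===================================================================

All quantities are expressed in the model's arbitrary units.  Time is a
dimensionless model unit (roughly one leptin-turnover time); an optional
minutes-per-unit conversion can be applied by the caller but nothing in the
package depends on it.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "PhasePoint",
    "PRESETS",
    "PRESET_SWEEPS",
    "load_parameters",
    "save_parameters",
    "expand_sweep",
    "random_valid_parameters",
]

_FIELDS = ("aF", "gammaF", "gammaE", "aL", "gammaL", "KL", "umax", "n")


@dataclass(frozen=True)
class ModelParameters:
    """Parameter set of the fat-leptin operating-point model.

    All rates must be strictly positive.  ``n`` must be >= 1 or ``math.inf``
    (the explicit infinitely-steep flag).  A positive-fat steady state exists
    only when ``aF * umax > gammaE`` -- this is checked by the operations that
    rely on it, not silently assumed here, so that e.g. sweeps may pass
    through infeasible corners while being reported as such.
    """

    aF: float = 0.02
    gammaF: float = 0.025
    gammaE: float = 0.00625
    aL: float = 1.0
    gammaL: float = 1.0
    KL: float = 0.5
    umax: float = 2.0
    n: float = math.inf

    def __post_init__(self) -> None:
        for name in _FIELDS[:-1]:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be a strictly positive finite number, got {value!r}")
        if not (self.n == math.inf or (math.isfinite(self.n) and self.n >= 1)):
            raise ValueError(f"Hill steepness n must be >= 1 or math.inf, got {self.n!r}")

    @property
    def hill_infinite(self) -> bool:
        """True when the infinitely steep (n -> inf) appetite rule is selected."""
        return math.isinf(self.n)

    @property
    def feasible_positive_fat(self) -> bool:
        """True when a positive-fat steady state can exist (aF*umax > gammaE)."""
        return self.aF * self.umax > self.gammaE

    def require_feasible(self) -> None:
        if not self.feasible_positive_fat:
            raise ValueError(
                "no positive-fat steady state: aF*umax = "
                f"{self.aF * self.umax:g} must exceed gammaE = {self.gammaE:g}"
            )

    def with_(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.n):
            d["n"] = "inf"
        return d


@dataclass(frozen=True)
class PhasePoint:
    """A point (fat mass F, food intake u) on the phase portrait."""

    F: float
    u: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError(f"fat mass must be non-negative, got {self.F!r}")
        if self.u < 0:
            raise ValueError(f"food intake must be non-negative, got {self.u!r}")


# ---------------------------------------------------------------------------
# Presets.  Keys follow the figure labels under which each parameter column is
# used; swept entries are [lo, hi] pairs kept verbatim in PRESET_SWEEPS and
# replaced by their midpoint in the scalar preset.
# ---------------------------------------------------------------------------

_RAW_PRESETS: dict[str, dict] = {
    "default": {},
    "fig3A": {"gammaE": 0.0134},                        # raised energy expenditure (exercise)
    "fig3B": {"KL": 0.75},                              # leptin resistance
    "fig4C": {"KL": 1.0},                               # leptin antagonist
    "fig4D": {"gammaE": 0.01875},                       # exercise adaptation
    "fig5B": {"aF": 0.01},
    "fig5CE": {"aF": 0.01, "KL": [0.35, 1.6]},          # KL sweep, above-critical regime
    "fig5D": {"aF": 0.01, "gammaL": 1.5, "KL": [0.1, 0.8]},
    # KL recorded as printed (3.6).  Note: 2*Kcrit of the default column is 5.4
    # with gammaL=1; 3.6 corresponds to gammaL=1.5 with aF=0.02.  The printed
    # value is kept and the discrepancy documented in docs/methods.md.
    "fig5F": {"aF": 0.01, "gammaL": 1.5, "KL": 3.6, "umax": [0.9, 2.7]},
}

_BASE = dict(aF=0.02, gammaF=0.025, gammaE=0.00625, aL=1.0, gammaL=1.0,
             KL=0.5, umax=2.0, n=math.inf)


def _split_preset(raw: dict) -> tuple[dict, dict]:
    scalars = dict(_BASE)
    sweeps: dict[str, tuple[float, float]] = {}
    for key, value in raw.items():
        if isinstance(value, (list, tuple)):
            lo, hi = float(value[0]), float(value[1])
            sweeps[key] = (lo, hi)
            scalars[key] = 0.5 * (lo + hi)
        else:
            scalars[key] = float(value)
    return scalars, sweeps


PRESETS: dict[str, ModelParameters] = {}
PRESET_SWEEPS: dict[str, dict[str, tuple[float, float]]] = {}
for _name, _raw in _RAW_PRESETS.items():
    _scalars, _sweeps = _split_preset(_raw)
    PRESETS[_name] = ModelParameters(**_scalars)
    PRESET_SWEEPS[_name] = _sweeps


def expand_sweep(preset: str, param: str | None = None, num: int = 9) -> list[ModelParameters]:
    """Expand a preset's swept range into `num` evenly spaced parameter sets.

    If the preset has exactly one swept parameter, `param` may be omitted.
    """
    if preset not in PRESET_SWEEPS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    sweeps = PRESET_SWEEPS[preset]
    if not sweeps:
        raise ValueError(f"preset {preset!r} has no swept parameters")
    if param is None:
        if len(sweeps) != 1:
            raise ValueError(f"preset {preset!r} sweeps {sorted(sweeps)}; specify param")
        param = next(iter(sweeps))
    lo, hi = sweeps[param]
    base = PRESETS[preset]
    return [base.with_(**{param: float(v)}) for v in np.linspace(lo, hi, num)]


def _coerce_n(value) -> float:
    if value in ("inf", "Infinity", None, ".inf"):
        return math.inf
    value = float(value)
    return value


def load_parameters(source: str | os.PathLike | dict) -> ModelParameters:
    """Load parameters from a preset name, a YAML/JSON file, or a mapping.

    Files must contain exactly the keys
    ``{aF, gammaF, gammaE, aL, gammaL, KL, umax, n}`` (``n`` may be the string
    ``"inf"``).  Unknown or missing keys are reported exhaustively and no
    partial object is produced.
    """
    if isinstance(source, dict):
        data = dict(source)
    elif isinstance(source, (str, os.PathLike)) and str(source) in PRESETS:
        return PRESETS[str(source)]
    else:
        path = str(source)
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"{path!r} is neither a preset name ({sorted(PRESETS)}) nor an existing file"
            )
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        if path.endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path!r} must contain a mapping, got {type(data).__name__}")

    problems = []
    missing = [k for k in _FIELDS if k not in data]
    extra = [k for k in data if k not in _FIELDS]
    if missing:
        problems.append(f"missing keys: {missing}")
    if extra:
        problems.append(f"unknown keys: {extra}")
    if problems:
        raise ValueError("invalid parameter mapping: " + "; ".join(problems))
    kwargs = {k: float(data[k]) for k in _FIELDS[:-1]}
    kwargs["n"] = _coerce_n(data["n"])
    return ModelParameters(**kwargs)


def save_parameters(p: ModelParameters, path: str | os.PathLike) -> None:
    """Write a parameter set as YAML (or JSON if the path ends in .json)."""
    data = p.to_dict()
    path = str(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def random_valid_parameters(rng: np.random.Generator, n: float = math.inf) -> ModelParameters:
    """Draw a random feasible parameter set (log-uniform around the defaults).

    Used by property tests and oracle cross-checks; guarantees
    ``aF*umax > gammaE`` so an operating point exists.
    """
    base = ModelParameters()
    while True:
        factors = {
            name: float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
            for name in ("aF", "gammaF", "gammaE", "aL", "gammaL", "KL", "umax")
        }
        p = ModelParameters(
            aF=base.aF * factors["aF"],
            gammaF=base.gammaF * factors["gammaF"],
            gammaE=base.gammaE * factors["gammaE"],
            aL=base.aL * factors["aL"],
            gammaL=base.gammaL * factors["gammaL"],
            KL=base.KL * factors["KL"],
            umax=base.umax * factors["umax"],
            n=n,
        )
        if p.feasible_positive_fat:
            return p
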