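import numpy as np
import pytest

from adipoint import ModelParameters


@pytest.fixture
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230125)


def grid_bisect_intersection(p: ModelParameters, n: float = float("inf"),
                             tol: float = 1e-12) -> float:
    """Independent oracle: bisection on diet-minus-appetite intake difference.

    Uses only the defining formulas (diet line u=(gammaF*F+gammaE)/aF; the
    steep-limit appetite rule, or the finite-n fixed point solved by its own
    inner bisection) -- no calls into the package's solvers.
    """
    import math

    def u_diet(F):
        return (p.gammaF * F + p.gammaE) / p.aF

    Fc = p.KL * p.gammaL / (p.aL * p.umax)

    def u_app(F):
        if math.isinf(n):
            return p.umax if F <= Fc else Fc * p.umax / F
        if F == 0:
            return p.umax
        k = p.aL / (p.gammaL * p.KL)

        def g(u):
            t = n * math.log(k * F * u)
            term = math.inf if t > 700 else math.exp(t)
            return u * (1.0 + term) - p.umax

        lo_u, hi_u = 1e-15 * p.umax, p.umax
        if g(hi_u) <= 0:
            return p.umax
        for _ in range(200):
            mid = 0.5 * (lo_u + hi_u)
            if g(mid) > 0:
                hi_u = mid
            else:
                lo_u = mid
        return 0.5 * (lo_u + hi_u)

    lo, hi = 0.0, (p.aF * p.umax - p.gammaE) / p.gammaF
    if u_diet(lo) - u_app(lo) >= 0:
        raise RuntimeError("no positive intersection")
    while u_diet(hi) - u_app(hi) < 0:
        hi *= 1.5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if u_diet(mid) - u_app(mid) >= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)
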