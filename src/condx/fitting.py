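"""Rate-parameter inference from double-positive time courses.

The double-positive (DP) count at reported time t is modeled as
Binomial(n_total(t), p(t)) with

    p(t) = (1 − φ) · CDF(t + dead_offset; k_on, k_bounce, k_entry),

where CDF is the closed-form first-passage distribution of the three-state
exchange model, φ is an optional immobile fraction and dead_offset the
mixing-to-acquisition dead time.  A single DP curve determines only two
exponential rates and a weight, so by default only the interface-resistance
rate k_bounce is free while k_on and k_entry stay fixed at their reference
values (0.05 and 0.1 s⁻¹); joint fits are opt-in and should be read together
with profile-likelihood diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitFailureError
from .kinetics import RateParameters, fpt_cdf

__all__ = [
    "Timecourse",
    "FitResult",
    "negative_log_likelihood",
    "fit_exchange",
    "profile_interval",
    "PARAM_BOUNDS",
]

#: Natural-scale box bounds per parameter (rates in s⁻¹, dead_offset in s).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "k_on": (1e-4, 1e2),
    "k_bounce": (1e-4, 1e2),
    "k_entry": (1e-4, 1e2),
    "phi": (0.0, 0.999),
    "dead_offset": (0.0, 60.0),
}

_RATE_NAMES = ("k_on", "k_bounce", "k_entry")
_DEFAULT_FIXED = {"k_on": 0.05, "k_entry": 0.1, "phi": 0.0, "dead_offset": 12.5}
_P_CLIP = 1e-12


@dataclass(frozen=True)
class Timecourse:
    """Double-positive counts per timepoint: times (s), n_total, n_dp."""

    times: np.ndarray
    n_total: np.ndarray
    n_dp: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_total, dtype=np.int64)
        k = np.asarray(self.n_dp, dtype=np.int64)
        if not (t.shape == n.shape == k.shape) or t.ndim != 1:
            raise DomainError("times, n_total, n_dp must be 1-D and equally long")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(t < 0):
            raise DomainError("times must be nonnegative")
        if np.any(k < 0) or np.any(k > n):
            raise DomainError("need 0 ≤ n_dp ≤ n_total at every timepoint")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_total", n)
        object.__setattr__(self, "n_dp", k)

    @classmethod
    def from_dataframe(cls, frame) -> "Timecourse":
        """Build from a DP-timecourse table (columns time_s, n_total, n_dp)."""
        return cls(
            times=frame["time_s"].to_numpy(),
            n_total=frame["n_total"].to_numpy(),
            n_dp=frame["n_dp"].to_numpy(),
        )


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the exchange model to a DP time course."""

    estimates: dict[str, float]
    fixed: dict[str, float]
    nll: float
    converged: bool
    at_bound: dict[str, str] = field(default_factory=dict)
    n_starts: int = 0
    profile_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        """All five model parameters, estimated and fixed combined."""
        return {**self.fixed, **self.estimates}


def _check_bounds(params: dict[str, float]) -> None:
    for name, value in params.items():
        if name not in PARAM_BOUNDS:
            raise DomainError(f"unknown parameter {name!r}")
        lo, hi = PARAM_BOUNDS[name]
        if name == "phi":
            ok = 0.0 <= value < 1.0
        elif name in _RATE_NAMES:
            ok = value > 0.0 and math.isfinite(value)
        else:
            ok = lo <= value <= hi
        if not ok:
            raise DomainError(f"parameter {name}={value!r} outside its domain")


def _dp_probability(params: dict[str, float], times: np.ndarray) -> np.ndarray:
    rates = RateParameters(params["k_on"], params["k_bounce"], params["k_entry"])
    p = (1.0 - params["phi"]) * fpt_cdf(times + params["dead_offset"], rates)
    return np.clip(p, _P_CLIP, 1.0 - _P_CLIP)


def negative_log_likelihood(
    params: dict[str, float],
    timecourse: Timecourse,
    fixed: dict[str, float] | None = None,
) -> float:
    """Binomial negative log-likelihood of a DP time course.

    ``params`` and ``fixed`` together must supply k_on, k_bounce, k_entry,
    phi and dead_offset; values in ``params`` take precedence.
    """
    full = {**_DEFAULT_FIXED, **(fixed or {}), **params}
    _check_bounds(full)
    p = _dp_probability(full, timecourse.times)
    logpmf = stats.binom.logpmf(timecourse.n_dp, timecourse.n_total, p)
    return float(-np.sum(logpmf))


def _transform(name: str, value: float) -> float:
    return math.log(value) if name in _RATE_NAMES else value


def _untransform(name: str, value: float) -> float:
    return math.exp(value) if name in _RATE_NAMES else value


def fit_exchange(
    timecourse: Timecourse,
    free: tuple[str, ...] = ("k_bounce",),
    fixed_values: dict[str, float] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of the free parameters by seeded multi-start
    bounded optimization (L-BFGS-B on log-transformed rates).

    ``free`` is a subset of {k_on, k_bounce, k_entry, phi, dead_offset};
    unlisted parameters take ``fixed_values`` overrides or the defaults
    (k_on = 0.05 s⁻¹, k_entry = 0.1 s⁻¹, φ = 0, dead_offset = 12.5 s).
    """
    free = tuple(free)
    for name in free:
        if name not in PARAM_BOUNDS:
            raise DomainError(f"unknown free parameter {name!r}")
    if len(timecourse.times) < len(free):
        raise DomainError(
            f"{len(free)} free parameters but only {len(timecourse.times)} timepoints"
        )
    fixed = {k: v for k, v in {**_DEFAULT_FIXED, **(fixed_values or {})}.items() if k not in free}

    bounds = []
    for name in free:
        lo, hi = PARAM_BOUNDS[name]
        if name in _RATE_NAMES:
            bounds.append((math.log(lo), math.log(hi)))
        elif name == "phi":
            bounds.append((0.0, 0.999))
        else:
            bounds.append((lo, hi))

    def objective(x: np.ndarray) -> float:
        params = {name: _untransform(name, xi) for name, xi in zip(free, x)}
        try:
            return negative_log_likelihood(params, timecourse, fixed)
        except DomainError:
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        x0 = []
        for (lo, hi), name in zip(bounds, free):
            if start == 0:
                # deterministic first start at the bounds' midpoint
                x0.append(0.5 * (lo + hi))
            else:
                x0.append(rng.uniform(lo, hi))
        res = optimize.minimize(
            objective, np.asarray(x0), method="L-BFGS-B", bounds=bounds
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(
            f"no optimization start converged ({n_starts} starts, free={free})"
        )

    estimates = {name: _untransform(name, xi) for name, xi in zip(free, best.x)}
    at_bound: dict[str, str] = {}
    for name, xi, (lo, hi) in zip(free, best.x, bounds):
        width = hi - lo
        if xi - lo < 1e-6 * width:
            at_bound[name] = "lower"
        elif hi - xi < 1e-6 * width:
            at_bound[name] = "upper"
    return FitResult(
        estimates=estimates,
        fixed=fixed,
        nll=float(best.fun),
        converged=True,
        at_bound=at_bound,
        n_starts=n_starts,
    )


def profile_interval(
    fit: FitResult,
    timecourse: Timecourse,
    param: str,
    level: float = 0.95,
) -> tuple[float, float, bool, bool]:
    """Profile-likelihood confidence interval for one fitted parameter.

    Scans the parameter away from its estimate, re-optimizing any other free
    parameters, until the profiled negative log-likelihood exceeds the
    optimum by χ²₁(level)/2; each crossing is then located by monotone
    bracketing (Brent).  Returns (lower, upper, open_lower, open_upper) —
    an open flag marks a profile that never crossed the threshold before
    hitting the parameter's bound.
    """
    if param not in fit.estimates:
        raise DomainError(f"{param!r} was not a free parameter of this fit")
    if not 0.0 <= level < 1.0:
        raise DomainError("level must be in [0, 1)")
    estimate = fit.estimates[param]
    if level == 0.0:
        return (estimate, estimate, False, False)
    threshold = fit.nll + 0.5 * stats.chi2.ppf(level, df=1)

    others = tuple(n for n in fit.estimates if n != param)
    lo_b, hi_b = PARAM_BOUNDS[param]
    is_rate = param in _RATE_NAMES

    def profile_nll(value: float) -> float:
        fixed = {**fit.fixed, param: value}
        if not others:
            try:
                return negative_log_likelihood({param: value}, timecourse, fit.fixed)
            except DomainError:
                return math.inf
        sub = fit_exchange(
            timecourse, free=others, fixed_values=fixed, n_starts=2, seed=0
        )
        return sub.nll

    def _scan(direction: int) -> tuple[float, bool]:
        bound = hi_b if direction > 0 else lo_b
        x = estimate
        prev = x
        for _ in range(200):
            if is_rate:
                x = x * (2.0 if direction > 0 else 0.5)
            else:
                step = 0.1 * max(abs(estimate), 0.05)
                x = x + direction * step
            if (direction > 0 and x >= bound) or (direction < 0 and x <= bound):
                x = bound if not (is_rate and bound == 0.0) else lo_b
                if profile_nll(x) < threshold:
                    return x, True  # open: threshold never crossed in range
                break
            if profile_nll(x) >= threshold:
                break
            prev = x
        root = optimize.brentq(lambda v: profile_nll(v) - threshold, *sorted((prev, x)))
        return float(root), False

    lower, open_lower = _scan(-1)
    upper, open_upper = _scan(+1)
    return (lower, upper, open_lower, open_upper)
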