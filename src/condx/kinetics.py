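"""Closed-form first-passage solutions of the three-state condensate exchange model.

A labeled protein exchanging into a preformed condensate is modeled as a
continuous-time Markov chain over three spatial states: the dilute phase
(surrounding solution), the interfacial layer (condensate surface), and the
dense phase (droplet interior).  Transitions are

    DILUTE --k_on--> INTERFACE --k_entry--> DENSE (absorbing)
    INTERFACE --k_bounce--> DILUTE

The interfacial layer acts as a kinetic barrier: ``k_bounce`` measures the
interface resistance and grows as condensates age and their surface
solidifies.  Starting from the dilute phase, the time to first reach the
dense phase is phase-type distributed with density

    F(t) = (k_on k_entry / Δ) (exp(-α₋ t) - exp(-α₊ t)),

where S = k_on + k_bounce + k_entry, Δ = sqrt(S² - 4 k_on k_entry) and
α± = (S ± Δ)/2.  The mean first-passage time is S / (k_on k_entry).

All rates are in s⁻¹ and all times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, InvalidParameterError

__all__ = [
    "RateParameters",
    "AgingScenario",
    "FptCurve",
    "AGING_PRESETS",
    "aging_preset",
    "fpt_density",
    "fpt_cdf",
    "fpt_laplace",
    "mfpt",
    "invert_cdf",
    "occupancy_solve",
    "fpt_curve",
]

# Relative discriminant below which the two eigenvalues are treated as equal
# and the degenerate (critically damped) closed form is used instead.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class RateParameters:
    """Transition rates of the three-state exchange model, in s⁻¹.

    Parameters
    ----------
    k_on
        Dilute phase → interfacial layer adsorption rate.
    k_bounce
        Interfacial layer → dilute phase return rate (interface resistance;
        increases with condensate aging).
    k_entry
        Interfacial layer → dense phase entry rate.
    """

    k_on: float
    k_bounce: float
    k_entry: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_bounce", "k_entry"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    @property
    def total(self) -> float:
        """S = k_on + k_bounce + k_entry."""
        return self.k_on + self.k_bounce + self.k_entry

    @property
    def discriminant(self) -> float:
        """Δ = sqrt(S² − 4 k_on k_entry); real for any positive rates."""
        d2 = self.total**2 - 4.0 * self.k_on * self.k_entry
        # provably ≥ 0: S² − 4 k_on k_entry ≥ (k_on + k_entry)² − 4 k_on k_entry
        #             = (k_on − k_entry)² ≥ 0; clamp tiny negative round-off
        return math.sqrt(max(d2, 0.0))

    @property
    def eigenrates(self) -> tuple[float, float]:
        """(α₋, α₊) = ((S−Δ)/2, (S+Δ)/2), the two relaxation rates."""
        s, d = self.total, self.discriminant
        alpha_plus = 0.5 * (s + d)
        # α₋ computed as product/α₊ to avoid cancellation when Δ ≈ S
        alpha_minus = self.k_on * self.k_entry / alpha_plus
        return alpha_minus, alpha_plus

    @property
    def is_degenerate(self) -> bool:
        """True when the two eigenvalues coincide to within round-off."""
        return self.discriminant < _DEGENERATE_RTOL * self.total


@dataclass(frozen=True)
class AgingScenario:
    """A named condensate-age condition and its rate parameters."""

    label: str
    rates: RateParameters


#: Aging presets: interface resistance k_bounce grows with condensate age
#: while adsorption and entry rates are held fixed.
AGING_PRESETS: dict[str, AgingScenario] = {
    label: AgingScenario(label, RateParameters(k_on=0.05, k_bounce=kb, k_entry=0.1))
    for label, kb in (("early", 0.01), ("intermediate", 0.1), ("late", 1.0))
}


def aging_preset(label: str) -> AgingScenario:
    """Return the preset scenario for ``label`` in {early, intermediate, late}."""
    try:
        return AGING_PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown aging preset {label!r}; choose from {sorted(AGING_PRESETS)}"
        ) from None


def _check_times(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise DomainError("times must be nonnegative")


def fpt_density(t, rates: RateParameters):
    """First-passage time density F(t) of entry into the dense phase, in s⁻¹.

    Evaluates (k_on k_entry / Δ)(e^{−α₋ t} − e^{−α₊ t}); when the two
    eigenvalues coincide, the degenerate limit k_on k_entry · t · e^{−St/2}.
    Vectorized over ``t``; underflows to exactly 0 for large ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    if rates.is_degenerate:
        out = rates.k_on * rates.k_entry * t_arr * np.exp(-0.5 * rates.total * t_arr)
    else:
        am, ap = rates.eigenrates
        pref = rates.k_on * rates.k_entry / rates.discriminant
        out = pref * (np.exp(-am * t_arr) - np.exp(-ap * t_arr))
        # the difference of exponentials can round to tiny negatives at large t
        out = np.maximum(out, 0.0)
    return out if t_arr.ndim else float(out)


def fpt_cdf(t, rates: RateParameters):
    """Probability that a protein has entered the dense phase by time ``t``.

    Term-wise integral of the two-exponential density, using α₊ α₋ =
    k_on k_entry:  CDF(t) = 1 − (α₊ e^{−α₋ t} − α₋ e^{−α₊ t}) / Δ.
    Exactly 0 at t = 0 and tends to 1 as t → ∞.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    if rates.is_degenerate:
        a = 0.5 * rates.total
        out = -np.expm1(-a * t_arr) - a * t_arr * np.exp(-a * t_arr)
    else:
        am, ap = rates.eigenrates
        d = rates.discriminant
        # 1 − (α₊ e^{−α₋t} − α₋ e^{−α₊t})/Δ, rearranged through expm1 so that
        # CDF(0) is exactly 0 and small-t values keep full relative precision
        out = -(ap * np.expm1(-am * t_arr) - am * np.expm1(-ap * t_arr)) / d
        out = np.clip(out, 0.0, 1.0)
    return out if t_arr.ndim else float(out)


def fpt_laplace(s, rates: RateParameters):
    """Laplace transform F̃(s) = k_on k_entry / (s(s + S) + k_on k_entry)."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise DomainError("Laplace variable s must be nonnegative")
    kk = rates.k_on * rates.k_entry
    out = kk / (s_arr * (s_arr + rates.total) + kk)
    return out if s_arr.ndim else float(out)


def mfpt(rates: RateParameters) -> float:
    """Mean first-passage time (k_on + k_bounce + k_entry)/(k_on k_entry), in s."""
    return rates.total / (rates.k_on * rates.k_entry)


def invert_cdf(u: float, rates: RateParameters) -> float:
    """Quantile of the first-passage distribution: t with CDF(t) = u.

    Bisection via Brent's method to |CDF(t) − u| < 1e−10; ``u`` must lie in
    [0, 1).  Monotone in ``u``.
    """
    from scipy.optimize import brentq

    if not 0.0 <= u < 1.0:
        raise DomainError(f"quantile level must be in [0, 1), got {u!r}")
    if u == 0.0:
        return 0.0
    # bracket: CDF is concave-increasing past its inflection; expand upper end
    hi = mfpt(rates)
    while fpt_cdf(hi, rates) < u:
        hi *= 2.0
    return float(brentq(lambda t: fpt_cdf(t, rates) - u, 0.0, hi, xtol=1e-12))


@dataclass(frozen=True)
class FptCurve:
    """First-passage density and CDF tabulated on a time grid."""

    times: np.ndarray
    density: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise DomainError("times must be a strictly increasing nonnegative grid")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        object.__setattr__(self, "cdf", np.asarray(self.cdf, dtype=float))


def fpt_curve(t_grid, rates: RateParameters) -> FptCurve:
    """Tabulate density and CDF of the exchange-time distribution on a grid."""
    t = np.asarray(t_grid, dtype=float)
    return FptCurve(times=t, density=fpt_density(t, rates), cdf=fpt_cdf(t, rates))


def occupancy_solve(t_grid, rates: RateParameters) -> np.ndarray:
    """Numerically integrate the forward master equation with absorbing dense state.

    Starting from P = (1, 0, 0) (all probability in the dilute phase), solves

        P_dil' = −k_on P_dil + k_bounce P_int
        P_int' =  k_on P_dil − (k_bounce + k_entry) P_int
        P_den' =  k_entry P_int

    with a stiff-capable solver at rtol 1e−9.  P_den(t) is the CDF of the
    first-passage time, so this serves as an independent numeric oracle for
    the closed forms.

    Returns an array of shape (len(t_grid), 3): columns (P_dilute,
    P_interface, P_dense).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise DomainError("t_grid must be a strictly increasing nonnegative grid")

    k_on, k_b, k_e = rates.k_on, rates.k_bounce, rates.k_entry

    def rhs(_t, p):
        p_dil, p_int, _ = p
        return [
            -k_on * p_dil + k_b * p_int,
            k_on * p_dil - (k_b + k_e) * p_int,
            k_e * p_int,
        ]

    t0, t1 = 0.0, float(t[-1])
    if t1 == 0.0:
        return np.array([[1.0, 0.0, 0.0]])
    sol = solve_ivp(
        rhs,
        (t0, t1),
        [1.0, 0.0, 0.0],
        t_eval=t,
        method="Radau",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - linear system, always integrable
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    return sol.y.T
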