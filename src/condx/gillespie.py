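"""Exact stochastic simulation (Gillespie / SSA) of the three-state exchange chain.

Serves as an independent stochastic oracle for the closed-form first-passage
results and as the microscopic engine behind the synthetic assay generator.
The chain has at most two active channels per state, so the direct (exact)
algorithm is used throughout; every entry point takes an explicit seed and
constructs its own generator, so identical inputs give bitwise identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import NonTerminationError
from .kinetics import RateParameters

__all__ = ["State", "ExchangeTrajectory", "simulate_trajectory", "sample_exchange_times"]

#: Hard cap on transition count per trajectory / per sampling batch; guards
#: pathological parameter choices (k_entry ≪ k_bounce) from spinning forever.
STEP_CAP = 10**7


class State(Enum):
    DILUTE = "dilute"
    INTERFACE = "interface"
    DENSE = "dense"


@dataclass(frozen=True)
class ExchangeTrajectory:
    """One realization of the chain from DILUTE to absorption in DENSE.

    ``states[0]`` is DILUTE, ``states[-1]`` is DENSE; ``transition_times[i]``
    is the time at which ``states[i+1]`` was entered, strictly increasing.
    """

    states: tuple[State, ...]
    transition_times: np.ndarray

    @property
    def exchange_time(self) -> float:
        """Absorption time: first entry into the dense phase, seconds."""
        return float(self.transition_times[-1])


def simulate_trajectory(rates: RateParameters, seed: int) -> ExchangeTrajectory:
    """Simulate one trajectory from the dilute phase to dense-phase absorption."""
    rng = np.random.default_rng(seed)
    k_on, k_b, k_e = rates.k_on, rates.k_bounce, rates.k_entry
    p_enter = k_e / (k_b + k_e)

    states = [State.DILUTE]
    times: list[float] = []
    t = 0.0
    current = State.DILUTE
    for _ in range(STEP_CAP):
        if current is State.DILUTE:
            t += rng.exponential(1.0 / k_on)
            current = State.INTERFACE
        else:  # INTERFACE
            t += rng.exponential(1.0 / (k_b + k_e))
            current = State.DENSE if rng.random() < p_enter else State.DILUTE
        states.append(current)
        times.append(t)
        if current is State.DENSE:
            return ExchangeTrajectory(tuple(states), np.asarray(times))
    raise NonTerminationError(
        f"trajectory not absorbed within {STEP_CAP} steps", n_steps=len(times)
    )


def sample_exchange_times(rates: RateParameters, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. first-passage (exchange) times, in seconds.

    Vectorized SSA: every cycle adds an Exp(k_on) dilute waiting time and an
    Exp(k_bounce + k_entry) interface waiting time to all still-active
    samples, then absorbs each with probability k_entry/(k_bounce + k_entry).
    Expected cost is O(n · S/(k_on·MFPT)) draws.
    """
    if n < 1:
        raise ValueError(f"n must be ≥ 1, got {n}")
    rng = np.random.default_rng(seed)
    k_on, k_b, k_e = rates.k_on, rates.k_bounce, rates.k_entry
    p_enter = k_e / (k_b + k_e)

    times = np.zeros(n)
    active = np.arange(n)
    steps = 0
    while active.size:
        m = active.size
        steps += 2 * m
        if steps > STEP_CAP:
            raise NonTerminationError(
                f"sampling exceeded {STEP_CAP} transitions with "
                f"{active.size}/{n} samples unabsorbed",
                n_steps=steps,
            )
        times[active] += rng.exponential(1.0 / k_on, size=m)
        times[active] += rng.exponential(1.0 / (k_b + k_e), size=m)
        absorbed = rng.random(m) < p_enter
        active = active[~absorbed]
    return times
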