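"""Synthetic two-color condensate exchange assays.

Emulates the flow-cytometry exchange experiment: preformed red-labeled
condensates are mixed with blue-labeled protein at t = 0, and tubes are
sampled repeatedly; each acquisition records ~10,000 droplet events with
red/blue fluorescence and scatter.  The blue signal of a droplet grows in
proportion to the fraction of its protein content already exchanged, which
for a single protein is the first-passage CDF of the three-state model —
so the population double-positive fraction carries the exchange kinetics.

Modeling choices (quenched disorder on the interface-resistance rate, one
dead-time draw per run, per-timepoint resampling of droplets) are documented
in the project methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import events as ev
from .errors import InvalidParameterError
from .kinetics import RateParameters, fpt_cdf, invert_cdf  # noqa: F401  (invert_cdf re-exported)

__all__ = [
    "ExchangeAssayConfig",
    "ExchangeAssayResult",
    "generate_exchange_assay",
    "generate_two_population",
    "generate_ifc_events",
    "default_gates",
    "invert_cdf",
]


@dataclass(frozen=True)
class ExchangeAssayConfig:
    """Configuration of a synthetic time-resolved exchange assay.

    Parameters
    ----------
    rates
        Exchange-model rates shared by all droplets (before heterogeneity).
    n_droplets_per_timepoint
        Events acquired per timepoint (cytometer stopping rule), default 10,000.
    timepoints
        Acquisition times in seconds since the *first* read (the reported
        axis excludes dead time, which is stored separately as ground truth).
    dead_time
        Seconds from mixing to first acquisition.  ``None`` (default) draws
        once per run from Uniform(10, 15).
    size_lognormal
        (μ_ln, σ_ln) of the droplet size distribution (arbitrary units).
    het_sigma
        Lognormal SD of a per-droplet multiplier on k_bounce (quenched
        interface heterogeneity); 0 disables.
    blue_scale, red_scale
        Saturating fluorescence per unit droplet size (a.u.).
    detect_fraction
        ε: fraction of a median droplet's saturating blue signal at the
        positivity threshold; in (0, 1).
    noise_cv
        Multiplicative measurement coefficient of variation per channel.
    autofluorescence
        Additive background per fluorescence channel (a.u.).
    red_decay
        Optional (δ, τ_d): red signal declines to (1 − δ) with timescale τ_d
        seconds after mixing, mimicking the slight red decrease seen on blue
        protein addition; ``None`` disables.
    immobile_fraction
        φ: fraction of droplets that never convert (default 0).
    include_morphology
        Emit ``area``/``aspect_ratio`` columns (imaging-cytometry scenarios).
    """

    rates: RateParameters
    n_droplets_per_timepoint: int = 10_000
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 660, 60))
    dead_time: float | None = None
    size_lognormal: tuple[float, float] = (0.0, 0.4)
    het_sigma: float = 0.3
    blue_scale: float = 1000.0
    red_scale: float = 1000.0
    detect_fraction: float = 0.5
    noise_cv: float = 0.05
    autofluorescence: float = 10.0
    red_decay: tuple[float, float] | None = None
    immobile_fraction: float = 0.0
    include_morphology: bool = False

    def __post_init__(self) -> None:
        problems = []
        if not isinstance(self.rates, RateParameters):
            problems.append("rates: expected RateParameters")
        if self.n_droplets_per_timepoint < 1:
            problems.append("n_droplets_per_timepoint: must be ≥ 1")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size < 1 or np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            problems.append("timepoints: must be nonnegative and strictly increasing")
        if self.dead_time is not None and self.dead_time < 0:
            problems.append("dead_time: must be nonnegative")
        if self.size_lognormal[1] < 0:
            problems.append("size_lognormal: σ_ln must be ≥ 0")
        if self.het_sigma < 0:
            problems.append("het_sigma: must be ≥ 0")
        if self.blue_scale <= 0 or self.red_scale <= 0:
            problems.append("blue_scale/red_scale: must be positive")
        if not 0.0 < self.detect_fraction < 1.0:
            problems.append("detect_fraction: must be in (0, 1)")
        if self.noise_cv < 0:
            problems.append("noise_cv: must be ≥ 0")
        if self.autofluorescence < 0:
            problems.append("autofluorescence: must be ≥ 0")
        if self.red_decay is not None and not (
            0.0 <= self.red_decay[0] <= 1.0 and self.red_decay[1] > 0
        ):
            problems.append("red_decay: require δ ∈ [0,1] and τ_d > 0")
        if not 0.0 <= self.immobile_fraction < 1.0:
            problems.append("immobile_fraction: must be in [0, 1)")
        if problems:
            raise InvalidParameterError(
                "invalid assay configuration: " + "; ".join(problems)
            )
        object.__setattr__(self, "timepoints", tuple(tp))


@dataclass(frozen=True)
class ExchangeAssayResult:
    """Generated assay: one event table per timepoint plus ground truth."""

    tables: list[pd.DataFrame]
    dead_time: float
    config: ExchangeAssayConfig

    def __iter__(self):
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


def _cdf_heterogeneous_kb(
    t: float, k_on: float, k_bounce: np.ndarray, k_entry: float
) -> np.ndarray:
    """First-passage CDF at scalar time ``t``, vectorized over k_bounce values.

    Same two-exponential closed form as :func:`condx.kinetics.fpt_cdf`;
    Δ² ≥ (k_on − k_entry)² > 0 here, so no degenerate branch is needed for
    distinct adsorption and entry rates.
    """
    s = k_on + k_bounce + k_entry
    d = np.sqrt(np.maximum(s**2 - 4.0 * k_on * k_entry, 0.0))
    ap = 0.5 * (s + d)
    am = k_on * k_entry / ap
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf = -(ap * np.expm1(-am * t) - am * np.expm1(-ap * t)) / d
        degenerate = d < 1e-9 * s
        if degenerate.any():
            a = 0.5 * s
            cdf = np.where(degenerate, -np.expm1(-a * t) - a * t * np.exp(-a * t), cdf)
    return np.clip(cdf, 0.0, 1.0)


def _scatter(size: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # phenomenological optical proxies: monotone power laws of size with
    # lognormal noise, deliberately not a Mie computation
    fsc = 200.0 * size**2.0 * rng.lognormal(0.0, 0.15, size.size)
    ssc = 120.0 * size**1.5 * rng.lognormal(0.0, 0.2, size.size)
    return fsc, ssc


def generate_exchange_assay(config: ExchangeAssayConfig, seed: int) -> ExchangeAssayResult:
    """Generate one synthetic exchange assay (one event table per timepoint).

    Droplet i at reported time t carries blue fraction
    fᵢ(t) = CDF(t + dead_time; k_bounce·ηᵢ) with ηᵢ ~ lognormal(0, het_sigma),
    zeroed for an immobile φ-fraction; red = red_scale·sᵢ·decay(t), blue =
    blue_scale·sᵢ·fᵢ(t), both with multiplicative noise and additive
    autofluorescence.  Droplets are drawn independently at every timepoint.
    """
    rng = np.random.default_rng(seed)
    dead = (
        float(rng.uniform(10.0, 15.0)) if config.dead_time is None else float(config.dead_time)
    )
    mu_ln, sigma_ln = config.size_lognormal
    n = config.n_droplets_per_timepoint
    tables: list[pd.DataFrame] = []

    for t in config.timepoints:
        size = rng.lognormal(mu_ln, sigma_ln, n) if sigma_ln > 0 else np.full(n, np.exp(mu_ln))
        if config.het_sigma > 0:
            eta = rng.lognormal(0.0, config.het_sigma, n)
            frac = _cdf_heterogeneous_kb(
                t + dead, config.rates.k_on, config.rates.k_bounce * eta, config.rates.k_entry
            )
        else:
            frac = np.full(n, fpt_cdf(t + dead, config.rates))
        if config.immobile_fraction > 0:
            frac[rng.random(n) < config.immobile_fraction] = 0.0

        decay = 1.0
        if config.red_decay is not None:
            delta, tau = config.red_decay
            decay = 1.0 - delta * (1.0 - np.exp(-(t + dead) / tau))

        def _noisy(x: np.ndarray) -> np.ndarray:
            if config.noise_cv > 0:
                x = x * (1.0 + config.noise_cv * rng.standard_normal(x.size))
            return np.maximum(x, 0.0)

        red = _noisy(config.red_scale * size * decay) + config.autofluorescence
        blue = _noisy(config.blue_scale * size * frac) + config.autofluorescence
        fsc, ssc = _scatter(size, rng)

        table = pd.DataFrame(
            {
                "time_s": np.full(n, float(t)),
                "fsc": fsc,
                "ssc": ssc,
                "red": red,
                "blue": blue,
            }
        )
        if config.include_morphology:
            table["area"] = np.pi * (size / 2.0) ** 2
            table["aspect_ratio"] = rng.beta(15.0, 1.5, n)
        table["droplet_id"] = np.arange(n, dtype=np.int64)
        tables.append(ev.validate_events(table))

    return ExchangeAssayResult(tables=tables, dead_time=dead, config=config)


def default_gates(config: ExchangeAssayConfig):
    """Quadrant thresholds matched to the generator's detection model.

    Blue threshold sits at ε × (saturating blue of a median-size droplet);
    red likewise, so fully red condensates are red-positive by construction.
    """
    from .cytometry import QuadrantGates

    median_size = float(np.exp(config.size_lognormal[0]))
    return QuadrantGates(
        red_threshold=config.detect_fraction * config.red_scale * median_size,
        blue_threshold=config.detect_fraction * config.blue_scale * median_size,
    )


def generate_two_population(
    n_background: int,
    n_condensate: int,
    mfi_background: float,
    mfi_condensate: float,
    cv: float,
    seed: int,
) -> pd.DataFrame:
    """Mixture of two lognormal intensity populations (formation/dissolution fixture).

    Returns an event table whose ``label`` column carries the ground-truth
    population ("background" or "condensate") for test assertions; the
    lognormal is parameterized so each population's arithmetic mean equals
    its requested MFI.
    """
    if n_background < 0 or n_condensate < 0:
        raise InvalidParameterError("population counts must be ≥ 0")
    if mfi_background < 0 or mfi_condensate < 0:
        raise InvalidParameterError("MFI values must be ≥ 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    def draw(n: int, mean: float) -> np.ndarray:
        if mean == 0 or n == 0:
            return np.zeros(n)
        mu = np.log(mean) - 0.5 * sigma**2
        return rng.lognormal(mu, sigma, n)

    red = np.concatenate([draw(n_background, mfi_background), draw(n_condensate, mfi_condensate)])
    labels = ["background"] * n_background + ["condensate"] * n_condensate
    n = n_background + n_condensate
    size = np.where(np.array(labels) == "condensate", 1.0, 0.2) if n else np.zeros(0)
    fsc, ssc = _scatter(np.asarray(size, dtype=float), rng)
    return ev.validate_events(
        pd.DataFrame(
            {
                "time_s": np.zeros(n),
                "fsc": fsc,
                "ssc": ssc,
                "red": red,
                "blue": np.zeros(n),
                "label": labels,
            }
        )
    )


def generate_ifc_events(
    n_condensate: int, n_debris: int, seed: int, debris_area: float = 0.5
) -> pd.DataFrame:
    """Imaging-cytometry fixture: round large condensates plus small debris.

    Condensates are near-round (aspect ratio Beta(15, 1.5), i.e. close to 1)
    with areas well above ``debris_area``; debris is small and irregular.
    ``label`` carries ground truth.
    """
    rng = np.random.default_rng(seed)
    area_c = rng.lognormal(np.log(20.0), 0.4, n_condensate)
    ar_c = rng.beta(15.0, 1.5, n_condensate)
    area_d = rng.lognormal(np.log(debris_area), 0.5, n_debris)
    ar_d = rng.beta(2.0, 2.0, n_debris)
    n = n_condensate + n_debris
    size = np.sqrt(np.concatenate([area_c, area_d]) / np.pi) * 2.0
    fsc, ssc = _scatter(size, rng)
    return ev.validate_events(
        pd.DataFrame(
            {
                "time_s": np.zeros(n),
                "fsc": fsc,
                "ssc": ssc,
                "red": 1000.0 * size,
                "blue": np.zeros(n),
                "area": np.concatenate([area_c, area_d]),
                "aspect_ratio": np.concatenate([ar_c, ar_d]),
                "label": ["condensate"] * n_condensate + ["debris"] * n_debris,
            }
        )
    )
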