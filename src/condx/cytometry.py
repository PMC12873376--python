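"""Event-data I/O and the cytometry analysis procedures.

Covers the analysis workflow for condensate cytometry: ungated mean
fluorescence intensity (MFI), two-color quadrant analysis, double-positive
time courses for exchange kinetics, a rectangular aspect-ratio/area gate
for imaging flow cytometry, and the unpaired two-tailed Student's t-test
used for condition comparisons.

Positivity at a quadrant threshold uses strict ``>``; a boundary event is
negative.  MFI defaults to the arithmetic mean of raw intensities over all
events with no gate applied (median available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ChannelMappingError,
    DomainError,
    EmptyGateError,
    FormatError,
    SchemaError,
)
from .events import read_events_csv, validate_events, write_events  # noqa: F401

__all__ = [
    "ChannelMap",
    "QuadrantGates",
    "QuadrantSummary",
    "read_events",
    "write_events",
    "compute_mfi",
    "quadrant_summary",
    "double_positive_timecourse",
    "ifc_gate",
    "t_test_two_sample",
]


@dataclass(frozen=True)
class ChannelMap:
    """Mapping from logical channels to file parameter names.

    FCS files name detectors (e.g. "YL1-A"), not dyes; a ChannelMap binds
    the logical {red, blue, fsc, ssc} channels to those names.  ``red`` and
    ``blue`` are mandatory for exchange analyses.
    """

    red: str
    blue: str
    fsc: str | None = None
    ssc: str | None = None

    def items(self):
        out = {"red": self.red, "blue": self.blue}
        if self.fsc is not None:
            out["fsc"] = self.fsc
        if self.ssc is not None:
            out["ssc"] = self.ssc
        return out.items()


@dataclass(frozen=True)
class QuadrantGates:
    """Red/blue positivity thresholds (a.u.); events above both are double-positive."""

    red_threshold: float
    blue_threshold: float

    def __post_init__(self) -> None:
        if self.red_threshold < 0 or self.blue_threshold < 0:
            raise DomainError("quadrant thresholds must be ≥ 0")


@dataclass(frozen=True)
class QuadrantSummary:
    """Counts and fractions of the four threshold-defined quadrants at one timepoint."""

    time_s: float
    n_total: int
    n_double_positive: int
    n_red_only: int
    n_blue_only: int
    n_double_negative: int

    def __post_init__(self) -> None:
        parts = (
            self.n_double_positive
            + self.n_red_only
            + self.n_blue_only
            + self.n_double_negative
        )
        if parts != self.n_total:
            raise ValueError("quadrant counts must partition the event set")

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_total
        if n == 0:
            return {k: float("nan") for k in ("double_positive", "red_only", "blue_only", "double_negative")}
        return {
            "double_positive": self.n_double_positive / n,
            "red_only": self.n_red_only / n,
            "blue_only": self.n_blue_only / n,
            "double_negative": self.n_double_negative / n,
        }

    @property
    def dp_fraction(self) -> float:
        return self.fractions["double_positive"]


def read_events(path, format: str = "csv", channel_map: ChannelMap | None = None) -> pd.DataFrame:
    """Read an event table from CSV or FCS, renaming channels to logical names.

    For FCS input a ``channel_map`` is required; for CSV it is optional
    (columns may already use the logical schema).
    """
    if format == "csv":
        events = read_events_csv(path) if channel_map is None else pd.read_csv(path)
    elif format == "fcs":
        from .fcs import read_fcs

        if channel_map is None:
            raise ChannelMappingError("FCS input requires a channel_map")
        events = read_fcs(path)
    else:
        raise FormatError(f"unknown event format {format!r}; use 'csv' or 'fcs'")

    if channel_map is not None:
        missing = {
            logical: name for logical, name in channel_map.items() if name not in events.columns
        }
        if missing:
            raise ChannelMappingError(
                f"channels not found in file: {missing}; available parameters: "
                f"{list(events.columns)}"
            )
        events = events.rename(columns={name: logical for logical, name in channel_map.items()})
        if "time_s" not in events.columns:
            events.insert(0, "time_s", 0.0)
        for col in ("fsc", "ssc"):
            if col not in events.columns:
                events[col] = 0.0
    return validate_events(events)


def compute_mfi(
    events: pd.DataFrame,
    channel: str,
    gate: Callable[[pd.DataFrame], pd.Series] | None = None,
    statistic: str = "mean",
) -> float:
    """Mean (default) or median fluorescence intensity of ``channel``.

    ``gate`` is an optional boolean predicate over the table; the default is
    no gating — every event is included.
    """
    if channel not in events.columns:
        raise SchemaError(f"no such channel {channel!r} in event table")
    values = events[channel]
    if gate is not None:
        values = values[np.asarray(gate(events), dtype=bool)]
    if len(values) == 0:
        raise EmptyGateError("gate selected zero events")
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(values.median())
    raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")


def quadrant_summary(
    events: pd.DataFrame, gates: QuadrantGates, time_s: float | None = None
) -> QuadrantSummary:
    """Classify events into the four red/blue quadrants (strict thresholds)."""
    validate_events(events)
    red_pos = events["red"].to_numpy() > gates.red_threshold
    blue_pos = events["blue"].to_numpy() > gates.blue_threshold
    if time_s is None:
        time_s = float(events["time_s"].iloc[0]) if len(events) else 0.0
    return QuadrantSummary(
        time_s=float(time_s),
        n_total=int(len(events)),
        n_double_positive=int(np.sum(red_pos & blue_pos)),
        n_red_only=int(np.sum(red_pos & ~blue_pos)),
        n_blue_only=int(np.sum(~red_pos & blue_pos)),
        n_double_negative=int(np.sum(~red_pos & ~blue_pos)),
    )


def double_positive_timecourse(
    tables: Iterable[pd.DataFrame], gates: QuadrantGates
) -> pd.DataFrame:
    """Per-timepoint quadrant summaries assembled into an ordered DP time series.

    Each input table must be single-timepoint; the output rows (one per
    timepoint, columns time_s / n_total / n_dp / dp_fraction plus the other
    quadrant counts) are required to be in strictly increasing time order.
    No smoothing is applied.
    """
    summaries = []
    for table in tables:
        t = float(table["time_s"].iloc[0])
        if not (table["time_s"] == t).all():
            raise DomainError("each event table must contain a single timepoint")
        summaries.append(quadrant_summary(table, gates, time_s=t))
    if len(summaries) < 2:
        raise DomainError("a timecourse needs at least two timepoints")
    times = [s.time_s for s in summaries]
    if np.any(np.diff(times) <= 0):
        raise DomainError("timepoints must be strictly increasing")
    return pd.DataFrame(
        {
            "time_s": times,
            "n_total": [s.n_total for s in summaries],
            "n_dp": [s.n_double_positive for s in summaries],
            "n_red_only": [s.n_red_only for s in summaries],
            "n_blue_only": [s.n_blue_only for s in summaries],
            "n_double_negative": [s.n_double_negative for s in summaries],
            "dp_fraction": [s.dp_fraction for s in summaries],
        }
    )


def ifc_gate(events: pd.DataFrame, aspect_min: float, area_min: float) -> pd.DataFrame:
    """Rectangular imaging-cytometry gate: keep round (aspect_ratio ≥ aspect_min)
    and large (area ≥ area_min) events.  Idempotent.

    Aspect ratio follows the convention 1 = perfectly round, decreasing
    toward 0 for elongated objects, so condensates sit near 1.
    """
    for col in ("area", "aspect_ratio"):
        if col not in events.columns:
            raise SchemaError(f"ifc_gate requires morphology column {col!r}")
    keep = (events["aspect_ratio"] >= aspect_min) & (events["area"] >= area_min)
    return events.loc[keep]


def t_test_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-tailed Student's t-test (equal variances pooled).

    Returns (t statistic, two-tailed p-value) with n_a + n_b − 2 degrees of
    freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
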