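"""Canonical event-table schema and delimited-text I/O.

An event table is a pandas DataFrame with one row per cytometry event and a
fixed, versioned column schema.  ``area``, ``aspect_ratio`` (imaging flow
cytometry morphology) and ``droplet_id``/``label`` (synthetic ground-truth
provenance) are optional.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = 1

#: Required columns, in canonical order.
CORE_COLUMNS = ["time_s", "fsc", "ssc", "red", "blue"]
#: Optional columns appended after the core, in canonical order.
OPTIONAL_COLUMNS = ["area", "aspect_ratio", "droplet_id", "label"]

_INTENSITY_COLUMNS = ["fsc", "ssc", "red", "blue"]


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check schema and basic physical invariants; returns the table unchanged."""
    missing = [c for c in CORE_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"event table is missing required columns {missing}")
    if len(events) and (events["time_s"] < 0).any():
        raise SchemaError("time_s must be nonnegative")
    for col in _INTENSITY_COLUMNS:
        if len(events) and (events[col] < 0).any():
            raise SchemaError(f"{col} intensities must be nonnegative")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as UTF-8 CSV with header, '.' decimal."""
    validate_events(events)
    cols = CORE_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in events.columns]
    events.loc[:, cols].to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    """Read an event table from CSV and validate the schema."""
    try:
        events = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        from .errors import FormatError

        raise FormatError(f"malformed event CSV {path}: {exc}") from exc
    if "droplet_id" in events.columns:
        events["droplet_id"] = events["droplet_id"].astype(np.int64, errors="ignore")
    return validate_events(events)
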