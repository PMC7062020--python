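"""Reading, validating and indexing PIT-tag detection streams.

A detection stream is a tidy table with one row per antenna read:
``timestamp`` (second resolution), ``location_id``, ``tag_id`` and
``location_type`` (``"feeder"`` or ``"box"``).  From the stream we derive
each bird's arrival date (first evidence of presence, detection or capture)
and its presence window — the contiguous interval from arrival to last
detection that serves as the denominator period for association indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ["timestamp", "location_id", "tag_id", "location_type"]
LOCATION_TYPES = frozenset({"feeder", "box"})


@dataclass
class DetectionStream:
    """A validated detection table plus bookkeeping about rejected input rows.

    ``data`` is sorted by (location_id, timestamp) and has one row per
    unique (timestamp, location_id, tag_id) triple.
    """

    data: pd.DataFrame
    n_rejected: int = 0
    rejected_lines: list[int] = field(default_factory=list)
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.data)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["location_id", "timestamp", "tag_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["date"] = df["timestamp"].dt.normalize()
    return df


def read_detections(path, season_span: tuple | None = None) -> DetectionStream:
    """Read a detections CSV, rejecting malformed rows instead of failing.

    Parameters
    ----------
    path
        CSV with columns timestamp, location_id, tag_id, location_type.
    season_span
        Optional (start, end) dates; rows outside the span are rejected
        and counted like malformed rows.

    Rows with unparseable timestamps, empty identifiers or unknown location
    types are dropped and their (1-based, header-inclusive) line numbers
    recorded.  Exact duplicate (timestamp, location, tag) reads collapse to
    a single record.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"detections file {path} missing columns: {missing}")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() | (raw["tag_id"].str.strip() == "") | (raw["location_id"].str.strip() == "")
    bad |= ~raw["location_type"].isin(LOCATION_TYPES)
    if season_span is not None:
        start = pd.Timestamp(season_span[0])
        end = pd.Timestamp(season_span[1]) + pd.Timedelta(days=1)
        with np.errstate(all="ignore"):
            bad |= ~ts.isna() & ((ts < start) | (ts >= end))

    rejected_lines = [int(i) + 2 for i in raw.index[bad]]  # +2: header + 1-based
    for line in rejected_lines:
        logger.warning("rejected detection row at line %d of %s", line, path)

    df = raw.loc[~bad, ["location_id", "tag_id", "location_type"]].copy()
    df.insert(0, "timestamp", ts[~bad])
    n_before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "location_id", "tag_id"])
    return DetectionStream(
        data=_finalize(df),
        n_rejected=len(rejected_lines),
        rejected_lines=rejected_lines,
        n_duplicates=n_before - len(df),
    )


def write_detections(df: pd.DataFrame, path) -> None:
    """Write a detection table in the canonical CSV schema (ISO-8601 times)."""
    out = df[COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def capture_records_from_individuals(individuals: pd.DataFrame, season_start) -> pd.DataFrame:
    """In-season capture records derived from tagging dates.

    A bird tagged on or after season start was caught in the study site on
    that day, which counts as evidence of presence for the arrival rule;
    earlier taggings carry no information about winter presence.
    """
    dates = pd.to_datetime(individuals["tagging_date"])
    keep = dates >= pd.Timestamp(season_start)
    return pd.DataFrame(
        {"tag_id": individuals.loc[keep, "tag_id"], "capture_date": dates[keep]}
    ).reset_index(drop=True)


def arrival_date(
    stream: pd.DataFrame,
    capture_records: pd.DataFrame | None,
    tag_id: str,
    season_start,
) -> pd.Timestamp | None:
    """First day an individual was known present: min of first detection
    date and first capture date, clipped to be no earlier than season start.

    Returns None for an individual never detected nor captured.
    """
    season_start = pd.Timestamp(season_start)
    candidates = []
    mine = stream.loc[stream["tag_id"] == tag_id, "timestamp"]
    if len(mine):
        candidates.append(mine.min().normalize())
    if capture_records is not None:
        caps = capture_records.loc[capture_records["tag_id"] == tag_id, "capture_date"]
        if len(caps):
            candidates.append(pd.to_datetime(caps).min().normalize())
    if not candidates:
        return None
    return max(min(candidates), season_start)


def presence_windows(
    stream: pd.DataFrame,
    capture_records: pd.DataFrame | None = None,
    season_start=None,
) -> pd.DataFrame:
    """Per-individual presence window [first_seen, last_seen].

    first_seen follows the arrival rule (detection or capture, clipped to
    season start); last_seen is the last detection date at any location.
    Individuals with captures but no detections get a zero-length window at
    their arrival date.
    """
    firsts = stream.groupby("tag_id")["timestamp"].min().dt.normalize()
    lasts = stream.groupby("tag_id")["timestamp"].max().dt.normalize()
    tags = set(firsts.index)
    if capture_records is not None and len(capture_records):
        caps = capture_records.assign(
            capture_date=pd.to_datetime(capture_records["capture_date"]).dt.normalize()
        ).groupby("tag_id")["capture_date"].min()
        tags |= set(caps.index)
    else:
        caps = pd.Series(dtype="datetime64[ns]")

    rows = []
    for tag in sorted(tags):
        cands = []
        if tag in firsts.index:
            cands.append(firsts[tag])
        if tag in caps.index:
            cands.append(caps[tag])
        first = min(cands)
        if season_start is not None:
            first = max(first, pd.Timestamp(season_start))
        last = lasts[tag] if tag in lasts.index else first
        rows.append((tag, first, max(first, last)))
    return pd.DataFrame(rows, columns=["tag_id", "first_seen", "last_seen"])
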