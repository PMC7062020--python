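"""Winter nest-box co-inspection by mixed-sex dyads.

Blue tits prospect nest-boxes during winter, and future pair members often
inspect boxes together.  Co-inspection is scored as a binary dyadic flag:
a dyad "inspected a box together" if, on some day at some box strictly
before the nest-building cutoff, both members were detected within a time
threshold of each other.  The threshold (default 60 s, inclusive) can be
calibrated from the observed minimum time differences between future
social mates at the same box on the same day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationSummary", "calibrate_threshold", "coinspection_flags"]


@dataclass
class CalibrationSummary:
    """Distribution of per-day, per-box minimum time differences (seconds)."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    differences: pd.DataFrame  # day, box, pair, min_diff_seconds


def _min_cross_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum |a_i - b_j| between two sorted arrays, by merge walk."""
    pos = np.searchsorted(b, a)
    best = np.inf
    for x, p in zip(a, pos):
        if p < len(b):
            best = min(best, abs(b[p] - x))
        if p > 0:
            best = min(best, abs(x - b[p - 1]))
    return float(best)


def _day_box_pair_diffs(box_stream: pd.DataFrame, dyads: list[tuple[str, str]]) -> pd.DataFrame:
    """Min time difference per (day, box, dyad) where both members visited."""
    from itertools import combinations

    wanted = {(a, b): (a, b) for a, b in dyads}
    wanted.update({(b, a): (a, b) for a, b in dyads})
    df = box_stream
    rows = []
    for (day, box), grp in df.groupby([df["timestamp"].dt.normalize(), "location_id"]):
        present = grp.groupby("tag_id")["timestamp"]
        times = {
            tag: np.sort(ts.to_numpy().astype("datetime64[s]").astype(np.int64))
            for tag, ts in present
        }
        for u, v in combinations(sorted(times), 2):
            key = wanted.get((u, v))
            if key is not None:
                a, b = key
                rows.append((day, box, a, b, _min_cross_diff(times[a], times[b])))
    return pd.DataFrame(rows, columns=["date", "box", "tag_a", "tag_b", "min_diff_seconds"])


def calibrate_threshold(
    box_stream: pd.DataFrame, social_pairs: list[tuple[str, str]]
) -> CalibrationSummary:
    """Summarize minimum female–male detection gaps for future social pairs.

    For every day × box where both members of a social pair were detected,
    the minimum absolute time difference between their reads is extracted;
    the summary over all such triples guides the co-inspection threshold.
    """
    diffs = _day_box_pair_diffs(box_stream, social_pairs)
    if diffs.empty:
        return CalibrationSummary(0, np.nan, np.nan, np.nan, np.nan, np.nan, diffs)
    v = diffs["min_diff_seconds"].to_numpy()
    return CalibrationSummary(
        n=len(v),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        differences=diffs,
    )


def coinspection_flags(
    box_stream: pd.DataFrame,
    dyads: list[tuple[str, str]],
    threshold_seconds: float = 60.0,
    cutoff_date=None,
) -> pd.DataFrame:
    """Binary co-inspection flag per dyad.

    A dyad is flagged when some day × box before ``cutoff_date``
    (exclusive: visits on the first nest-building day do not count) has
    detections of both members within ``threshold_seconds`` (inclusive).
    Returns tag_a, tag_b, coinspect, n_joint_days.
    """
    if threshold_seconds <= 0:
        raise ValueError("threshold must be positive")
    df = box_stream
    if cutoff_date is not None:
        df = df[df["timestamp"].dt.normalize() < pd.Timestamp(cutoff_date)]
    diffs = _day_box_pair_diffs(df, dyads)
    rows = []
    for a, b in dyads:
        mine = diffs[(diffs["tag_a"] == a) & (diffs["tag_b"] == b)]
        hits = mine[mine["min_diff_seconds"] <= threshold_seconds]
        rows.append((a, b, len(hits) > 0, hits["date"].nunique()))
    return pd.DataFrame(rows, columns=["tag_a", "tag_b", "coinspect", "n_joint_days"])
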