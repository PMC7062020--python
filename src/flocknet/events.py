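"""Segmenting per-location, per-day detection sequences into flocking events.

Birds visit feeders in bursts: a gathering ("flocking event") shows up as a
dense cluster of reads separated from the next cluster by a quiet gap.  Two
detectors are provided:

* :func:`detect_events_gmm` — fits 1-D Gaussian mixtures over detection
  times, selects the number of components by BIC and hard-assigns each
  detection to its maximum-responsibility component.  This mirrors the
  mixture-model approach standard for RFID gathering-event data.
* :func:`detect_events_gap` — splits wherever consecutive detections are
  more than ``gap_seconds`` apart.  Transparent and fast; on well-separated
  bursts it produces the same partition as the mixture detector and serves
  as its independent check.

Both operate on a single location-day; :func:`detect_all_events` maps a
detector over a whole stream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlockEvent:
    """A temporal cluster of detections at one location with its member set."""

    location_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    members: frozenset
    detection_count: int

    @property
    def date(self) -> pd.Timestamp:
        return self.start.normalize()


def _events_from_labels(df: pd.DataFrame, labels: np.ndarray) -> list[FlockEvent]:
    events = []
    for lab in np.unique(labels):
        sub = df[labels == lab]
        events.append(
            FlockEvent(
                location_id=str(sub["location_id"].iloc[0]),
                start=sub["timestamp"].min(),
                end=sub["timestamp"].max(),
                members=frozenset(sub["tag_id"]),
                detection_count=len(sub),
            )
        )
    events.sort(key=lambda e: (e.start, e.end))
    return events


def _check_one_location_day(df: pd.DataFrame) -> None:
    if df["location_id"].nunique() > 1:
        raise ValueError("stream spans multiple locations")
    if df["timestamp"].dt.normalize().nunique() > 1:
        raise ValueError("stream spans multiple days")


def detect_events_gap(location_day_stream: pd.DataFrame, gap_seconds: float = 600.0) -> list[FlockEvent]:
    """Split a sorted location-day stream at quiet gaps longer than ``gap_seconds``."""
    df = location_day_stream
    if df.empty:
        return []
    _check_one_location_day(df)
    df = df.sort_values("timestamp", kind="mergesort")
    t = df["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64)
    breaks = np.diff(t) > gap_seconds
    labels = np.concatenate([[0], np.cumsum(breaks)])
    return _events_from_labels(df, labels)


def _merge_contiguous(labels: np.ndarray, t: np.ndarray, merge_factor: float) -> np.ndarray:
    """Merge time-adjacent clusters separated by a near-typical gap.

    A flat (uniform-shaped) burst is cheaper to encode as several narrow
    Gaussians than one wide one, so BIC alone over-splits it.  The median
    positive inter-detection gap of the location-day estimates the
    within-burst spacing (most gaps are within bursts); clusters closer
    than ``merge_factor`` times that spacing belong to one gathering,
    while genuinely separate bursts sit far beyond it.
    """
    gaps = np.diff(np.sort(t))
    gaps = gaps[gaps > 0]
    if gaps.size == 0:
        return np.zeros_like(labels)
    threshold = merge_factor * np.median(gaps)
    order = np.argsort([t[labels == lab].min() for lab in np.unique(labels)])
    clusters = [np.flatnonzero(labels == lab) for lab in np.unique(labels)[order]]
    merged = [clusters[0]]
    for cl in clusters[1:]:
        prev = merged[-1]
        if t[cl].min() - t[prev].max() <= threshold:
            merged[-1] = np.concatenate([prev, cl])
        else:
            merged.append(cl)
    out = np.empty_like(labels)
    for k, cl in enumerate(merged):
        out[cl] = k
    return out


def detect_events_gmm(
    location_day_stream: pd.DataFrame,
    max_components: int = 20,
    min_detections: int = 2,
    seed: int = 0,
    merge_factor: float = 10.0,
) -> list[FlockEvent]:
    """Mixture-model event detection on one location-day.

    Fits Gaussian mixtures with K = 1..min(max_components, n) components to
    the detection times (seconds within the day), picks K by BIC, and turns
    each non-empty component into one event.  Component means are
    initialized at quantile-spaced positions so that, with a fixed seed,
    output is deterministic; responsibility ties break toward the earlier
    component.  Time-adjacent components are merged when their gap is
    below ``merge_factor`` times the component spread (see
    :func:`_merge_contiguous`); set ``merge_factor=0`` for raw BIC output.

    Streams with fewer than ``min_detections`` reads fall back to a single
    event containing everything.
    """
    df = location_day_stream
    if df.empty:
        return []
    _check_one_location_day(df)
    df = df.sort_values("timestamp", kind="mergesort")
    n = len(df)
    t = df["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64)
    t = (t - t.min()).astype(float)

    if n < min_detections:
        logger.info("location-day with %d < %d detections: single-event fallback", n, min_detections)
        return _events_from_labels(df, np.zeros(n, dtype=int))

    x = t.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, min(max_components, n) + 1):
        means = np.quantile(t, (np.arange(k) + 0.5) / k).reshape(-1, 1)
        try:
            with warnings.catch_warnings():
                # duplicate timestamps routinely collapse k-means init points
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm = GaussianMixture(
                    n_components=k,
                    means_init=means,
                    reg_covar=1.0,
                    random_state=seed,
                    max_iter=200,
                ).fit(x)
        except ValueError:  # degenerate fit for this K
            continue
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    if best is None:
        return _events_from_labels(df, np.zeros(n, dtype=int))

    resp = best.predict_proba(x)
    # order components by mean so "earlier component" is well defined
    order = np.argsort(best.means_.ravel(), kind="stable")
    resp = resp[:, order]
    # argmax returns the first (earliest-mean) component on exact ties
    labels = np.argmax(np.round(resp, 12), axis=1)
    if merge_factor > 0 and len(np.unique(labels)) > 1:
        labels = _merge_contiguous(labels, t, merge_factor)
    return _events_from_labels(df, labels)


def iter_location_days(stream: pd.DataFrame):
    """Yield (location_id, date, sub-stream) for each location-day, sorted."""
    df = stream.copy()
    if "date" not in df.columns:
        df["date"] = df["timestamp"].dt.normalize()
    for (loc, day), sub in df.groupby(["location_id", "date"], sort=True):
        yield loc, day, sub.sort_values("timestamp", kind="mergesort")


def detect_all_events(
    stream: pd.DataFrame,
    detector: str = "gap",
    gap_seconds: float = 600.0,
    max_components: int = 20,
    min_detections: int = 2,
    seed: int = 0,
) -> list[FlockEvent]:
    """Run an event detector over every location-day of a stream."""
    events: list[FlockEvent] = []
    for _, _, sub in iter_location_days(stream):
        if detector == "gap":
            events.extend(detect_events_gap(sub, gap_seconds=gap_seconds))
        elif detector == "gmm":
            events.extend(
                detect_events_gmm(
                    sub, max_components=max_components, min_detections=min_detections, seed=seed
                )
            )
        else:
            raise ValueError(f"unknown detector {detector!r}")
    events.sort(key=lambda e: (e.start, e.location_id))
    return events


def events_to_group_matrix(
    events: list[FlockEvent], individuals: list[str]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary event-by-individual membership matrix plus per-event metadata.

    Raises if any event member is missing from ``individuals``.
    """
    index = {tag: i for i, tag in enumerate(individuals)}
    unknown = sorted({m for e in events for m in e.members} - set(index))
    if unknown:
        raise ValueError(f"event members not in individual list: {unknown}")
    mat = np.zeros((len(events), len(individuals)), dtype=np.int8)
    meta = []
    for row, ev in enumerate(events):
        for m in ev.members:
            mat[row, index[m]] = 1
        meta.append((ev.location_id, ev.date, ev.start, ev.end, ev.detection_count))
    meta_df = pd.DataFrame(
        meta, columns=["location_id", "date", "start", "end", "detection_count"]
    )
    return mat, meta_df


def events_to_frame(events: list[FlockEvent]) -> pd.DataFrame:
    """Long-format event table (members semicolon-joined) for CSV export."""
    rows = [
        (
            e.location_id,
            e.date.strftime("%Y-%m-%d"),
            e.start.strftime("%Y-%m-%dT%H:%M:%S"),
            e.end.strftime("%Y-%m-%dT%H:%M:%S"),
            ";".join(sorted(e.members)),
            e.detection_count,
        )
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["location_id", "date", "start", "end", "members", "detection_count"]
    )
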