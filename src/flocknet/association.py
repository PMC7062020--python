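"""Dyadic association indices from flocking events.

The central quantity is the simple ratio index (SRI) for a dyad (A, B):

    S_AB = x / (x + y_AB + y_A + y_B)

where ``x`` counts flocking events containing both birds, ``y_A`` (``y_B``)
counts events containing A without B (B without A) during the period both
were known to be in the study site, and ``y_AB`` counts occasions the two
were detected at the same time but at different locations (operationalized
as time-overlapping events at different feeders).  S_AB ranges from 0
(never associated) to 1 (always associated).

Because raw SRI distributions are focal-specific, the network statistic
used downstream is a rank transform: each focal bird's associates are
ranked by SRI (ascending, average ranks on ties), ranks are shifted to
start at 0 and divided by their maximum, and the dyadic *winter
association strength* is the mean of the two directed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .events import FlockEvent, detect_all_events
from .io import presence_windows

__all__ = [
    "AssociationMatrix",
    "association_counts",
    "sri",
    "sri_matrix",
    "directed_rank_transform",
    "ranked_strength",
    "spatial_overlap",
    "build_network",
    "last_feeder",
]


@dataclass
class AssociationMatrix:
    """Symmetric SRI and ranked-strength matrices over an ordered id list."""

    ids: list[str]
    sri: np.ndarray
    strength: np.ndarray
    window: str = "full"
    counts: pd.DataFrame | None = None

    def index(self, tag: str) -> int:
        return self.ids.index(tag)

    def strength_of(self, a: str, b: str) -> float:
        return float(self.strength[self.index(a), self.index(b)])


def sri(x: float, y_ab: float, y_a: float, y_b: float) -> float:
    """Simple ratio index for one dyad; defined as 0 when no events exist."""
    if min(x, y_ab, y_a, y_b) < 0:
        raise ValueError("association counts must be non-negative")
    denom = x + y_ab + y_a + y_b
    return x / denom if denom > 0 else 0.0


def association_counts(
    events: list[FlockEvent],
    presence: pd.DataFrame,
    same_time_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Per-dyad association counts (x, y_AB, y_A, y_B) from an event list.

    ``presence`` gives each bird's [first_seen, last_seen] window; solo
    counts y_A, y_B are restricted to days inside the intersection of the
    two windows, the denominator period over which both birds were
    observable.  Dyads whose windows are disjoint are flagged
    ``co_present = False`` with all counts zero.

    y_AB pairs two events at *different* locations whose time spans overlap
    by more than ``same_time_tolerance`` seconds, one containing A (not B)
    and the other B (not A); each overlapping event pair counts once.
    """
    tags = list(presence["tag_id"])
    idx = {t: i for i, t in enumerate(tags)}
    n = len(tags)
    first = presence["first_seen"].to_numpy().astype("datetime64[D]").astype(np.int64)
    last = presence["last_seen"].to_numpy().astype("datetime64[D]").astype(np.int64)

    ev_dates = np.array(
        [e.date.to_datetime64().astype("datetime64[D]").astype(np.int64) for e in events],
        dtype=np.int64,
    )
    unknown = sorted({m for e in events for m in e.members} - set(idx))
    if unknown:
        raise ValueError(f"event members without presence windows: {unknown}")

    # per-individual and per-shared-dyad event date lists
    solo_dates: list[list[int]] = [[] for _ in range(n)]
    shared_dates: dict[tuple[int, int], list[int]] = {}
    member_idx: list[np.ndarray] = []
    for k, e in enumerate(events):
        mem = sorted(idx[m] for m in e.members)
        member_idx.append(np.array(mem, dtype=np.intp))
        d = ev_dates[k]
        for i in mem:
            solo_dates[i].append(d)
        for a_pos in range(len(mem)):
            for b_pos in range(a_pos + 1, len(mem)):
                shared_dates.setdefault((mem[a_pos], mem[b_pos]), []).append(d)

    solo_arr = [np.sort(np.array(v, dtype=np.int64)) for v in solo_dates]
    shared_arr = {k: np.sort(np.array(v, dtype=np.int64)) for k, v in shared_dates.items()}

    # same-time-different-place pairs via a sweep over start-sorted events
    starts = np.array([e.start.value for e in events], dtype=np.int64) / 1e9
    ends = np.array([e.end.value for e in events], dtype=np.int64) / 1e9
    order = np.argsort(starts, kind="mergesort")
    simul_dates: dict[tuple[int, int], list[int]] = {}
    for pos, ei in enumerate(order):
        for fj in order[pos + 1 :]:
            if starts[fj] >= ends[ei] - same_time_tolerance:
                break
            if events[ei].location_id == events[fj].location_id:
                continue
            if min(ends[ei], ends[fj]) - max(starts[ei], starts[fj]) <= same_time_tolerance:
                continue
            mi, mj = member_idx[ei], member_idx[fj]
            only_i = np.setdiff1d(mi, mj, assume_unique=True)
            only_j = np.setdiff1d(mj, mi, assume_unique=True)
            d = ev_dates[ei]
            for a in only_i:
                for b in only_j:
                    key = (a, b) if a < b else (b, a)
                    simul_dates.setdefault(key, []).append(d)

    rows = []
    empty = np.array([], dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            w0 = max(first[i], first[j])
            w1 = min(last[i], last[j])
            co_present = w0 <= w1
            if not co_present:
                rows.append((tags[i], tags[j], 0, 0, 0, 0, False))
                continue
            sh = shared_arr.get((i, j), empty)
            x = int(np.searchsorted(sh, w1, "right") - np.searchsorted(sh, w0, "left"))
            ya = int(
                np.searchsorted(solo_arr[i], w1, "right")
                - np.searchsorted(solo_arr[i], w0, "left")
            ) - x
            yb = int(
                np.searchsorted(solo_arr[j], w1, "right")
                - np.searchsorted(solo_arr[j], w0, "left")
            ) - x
            sim = simul_dates.get((i, j))
            if sim is None:
                yab = 0
            else:
                sim = np.asarray(sim, dtype=np.int64)
                yab = int(((sim >= w0) & (sim <= w1)).sum())
            rows.append((tags[i], tags[j], x, yab, ya, yb, True))
    df = pd.DataFrame(
        rows, columns=["tag_a", "tag_b", "x", "y_ab", "y_a", "y_b", "co_present"]
    )
    df["sri"] = [sri(x, yab, ya, yb) for x, yab, ya, yb in zip(df.x, df.y_ab, df.y_a, df.y_b)]
    return df


def sri_matrix(counts: pd.DataFrame, ids: list[str]) -> np.ndarray:
    """Square symmetric SRI matrix (zero diagonal) from a long dyad table."""
    idx = {t: i for i, t in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    ai = counts["tag_a"].map(idx).to_numpy()
    bi = counts["tag_b"].map(idx).to_numpy()
    mat[ai, bi] = counts["sri"].to_numpy()
    mat[bi, ai] = counts["sri"].to_numpy()
    return mat


def directed_rank_transform(sri_values: np.ndarray) -> tuple[np.ndarray, float]:
    """Rank a focal bird's associate SRI values and normalize to [0, 1].

    Ascending average ranks, minus one, divided by the maximum shifted rank
    (the number of associates minus one).  Returns the normalized values
    and the divisor.  A single associate is trivially the strongest
    (value 1, divisor 1).
    """
    m = len(sri_values)
    if m == 0:
        return np.array([]), 1.0
    if m == 1:
        return np.array([1.0]), 1.0
    ranks = rankdata(sri_values, method="average")
    divisor = float(m - 1)
    return (ranks - 1.0) / divisor, divisor


def ranked_strength(sri_mat: np.ndarray) -> np.ndarray:
    """Dyadic winter association strength from a square SRI matrix.

    Each focal's row (excluding self) is rank-transformed; the dyadic
    strength is the mean of the two directed values.
    """
    n = sri_mat.shape[0]
    directed = np.zeros_like(sri_mat, dtype=float)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        vals, _ = directed_rank_transform(sri_mat[i, mask[i]])
        directed[i, mask[i]] = vals
    strength = (directed + directed.T) / 2.0
    np.fill_diagonal(strength, 0.0)
    return strength


def spatial_overlap(
    feeder_stream: pd.DataFrame, ids: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Summed-minimum overlap of per-individual feeder-use distributions.

    p_i(l) is the fraction of i's feeder detections at location l;
    overlap(A, B) = sum_l min(p_A(l), p_B(l)), from 0 (disjoint use) to 1
    (identical distributions).  Detection counts proxy time spent.
    Individuals with no feeder detections get overlap 0 with everyone.
    """
    usage = pd.crosstab(feeder_stream["tag_id"], feeder_stream["location_id"])
    if ids is None:
        ids = list(usage.index)
    usage = usage.reindex(ids, fill_value=0).to_numpy(dtype=float)
    totals = usage.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, usage / totals, 0.0)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        out[i] = np.minimum(p[i], p).sum(axis=1)
    np.fill_diagonal(out, 0.0)
    return list(ids), out


def last_feeder(feeder_stream: pd.DataFrame) -> pd.Series:
    """Last feeder each bird was recorded at (tag_id -> location_id)."""
    df = feeder_stream.sort_values("timestamp", kind="mergesort")
    return df.groupby("tag_id")["location_id"].last()


def build_network(
    stream: pd.DataFrame,
    capture_records: pd.DataFrame | None = None,
    window: tuple | None = None,
    detector: str = "gap",
    gap_seconds: float = 600.0,
    gmm_max_components: int = 20,
    gmm_min_detections: int = 2,
    seed: int = 0,
    season_start=None,
    presence_from: str = "both",
    label: str = "full",
) -> AssociationMatrix:
    """Full chain from a detection stream to an association matrix.

    Optionally restricts to a [start, end] date window, re-deriving
    presence windows and events inside it.  Events come from feeder
    detections; presence uses feeder and box detections by default
    (``presence_from`` = "both" | "feeder").
    """
    df = stream
    if window is not None:
        w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        dates = df["timestamp"].dt.normalize()
        df = df[(dates >= w0) & (dates <= w1)]
        season_start = w0 if season_start is None else max(pd.Timestamp(season_start), w0)
        if capture_records is not None and len(capture_records):
            cd = pd.to_datetime(capture_records["capture_date"])
            capture_records = capture_records[(cd >= w0) & (cd <= w1)]

    presence_src = df if presence_from == "both" else df[df["location_type"] == "feeder"]
    presence = presence_windows(presence_src, capture_records, season_start=season_start)
    feeder_df = df[df["location_type"] == "feeder"]
    events = detect_all_events(
        feeder_df,
        detector=detector,
        gap_seconds=gap_seconds,
        max_components=gmm_max_components,
        min_detections=gmm_min_detections,
        seed=seed,
    )
    counts = association_counts(events, presence)
    ids = list(presence["tag_id"])
    smat = sri_matrix(counts, ids)
    strength = ranked_strength(smat)
    return AssociationMatrix(ids=ids, sri=smat, strength=strength, window=label, counts=counts)
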