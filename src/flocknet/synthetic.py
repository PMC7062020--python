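"""Seeded synthetic winter colony with known planted social structure.

Field datasets of this kind (PIT-tagged songbirds visiting feeders and
nest-boxes over a winter, followed by a monitored breeding season) are
rarely public, so every downstream stage is validated against a simulator
with known ground truth.  The generative model:

* Each bird has a fixed home centre; feeder use decays exponentially with
  distance (``spatial_kernel_scale``).
* A latent symmetric affinity couples spatial proximity with an
  individual-pair random component.  Flock membership is sampled
  sequentially: a seed bird is drawn by spatial weight, further members by
  spatial weight times (1 + ``affinity_strength`` x mean affinity to birds
  already in the flock).  This reproduces flock-level assortment without
  explicit movement simulation.
* Arrival is staggered uniformly over the first ``arrival_window_days``
  days; a bird emits no detections before its arrival.
* Social pairs form by a female-choice softmax on affinity
  (``pairing_beta``); nests sit near the pair's home midpoint, so birds
  with high affinity (who also flock together) nest close — the planted
  spatial carry-over.
* Extra-pair paternity flags are drawn from a logistic model whose
  covariates are the *realized* dyadic quantities (neighbourhood order,
  male age, winter association strength, co-inspection), computed with the
  package's own analysis modules and 2-SD scaled, so recovery studies can
  compare fitted coefficients against ``epp_betas`` exactly.

Same config + same seed gives bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from . import association, coinspection, geometry, io

__all__ = ["ColonyConfig", "GroundTruth", "Colony", "simulate_colony", "write_colony",
           "simulate_dyad_table", "DEFAULT_EPP_BETAS"]

# planted extra-pair paternity model on the 2-SD-scaled realized covariates.
# Slopes follow the effect sizes reported for this study system (strong
# distance decay, adult-male and association-strength advantages, a modest
# co-inspection effect, no arrival-difference effect); the intercept is set
# so that a colony of the default size realizes a few-percent dyadic EPP
# rate, matching the prevalence regime of the field data.
DEFAULT_EPP_BETAS = {
    "intercept": -1.5,
    "order": -2.48,
    "male_age": 0.7,
    "strength": 1.0,
    "arrival_diff": 0.0,
    "coinspection": 0.4,
}


@dataclass
class ColonyConfig:
    """Parameters of the synthetic colony.

    Defaults emulate the field design the pipeline targets: a ~40 ha site
    with 20 feeders, a 1 Nov – 14 Mar winter, about 15 flocking events per
    feeder-day with mean flock size 4, and staggered arrival over the
    first 60 days.
    """

    n_individuals: int = 120
    n_feeders: int = 20
    n_boxes: int = 80
    site_extent: tuple = (0.0, 0.0, 640.0, 625.0)  # metres; 40 ha
    season_start: str = "2017-11-01"
    season_end: str = "2018-03-14"  # nest-building cutoff; detections end the day before
    arrival_window_days: int = 60
    affinity_strength: float = 8.0
    spatial_kernel_scale: float = 150.0
    events_per_feeder_day: float = 15.0
    mean_flock_size: float = 4.0
    event_duration_seconds: float = 120.0
    min_event_gap_seconds: float = 900.0
    extra_detections_mean: float = 1.0
    nonbreeder_fraction: float = 0.15
    pairing_beta: float = 6.0
    pair_bond_boost: float = 3.0
    epp_betas: dict = field(default_factory=lambda: dict(DEFAULT_EPP_BETAS))
    min_nest_spacing: float = 25.0
    nest_jitter: float = 60.0
    pair_coinspect_prob: float = 0.6
    nonpair_coinspect_rate: float = 1.0
    solo_box_visits_mean: float = 4.0
    max_order: int = 5
    coinspection_threshold_seconds: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_individuals, self.n_feeders, self.n_boxes) <= 0:
            raise ValueError("counts must be positive")
        x0, y0, x1, y1 = self.site_extent
        if (x1 - x0) * (y1 - y0) <= 0:
            raise ValueError("site extent must have positive area")
        if pd.Timestamp(self.season_end) <= pd.Timestamp(self.season_start):
            raise ValueError("season span is empty")

    @property
    def n_days(self) -> int:
        return (pd.Timestamp(self.season_end) - pd.Timestamp(self.season_start)).days


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst would estimate."""

    affinity: np.ndarray
    home_centres: np.ndarray
    tags: list[str]
    social_pairs: list[tuple[str, str]]
    epp_dyads: list[tuple[str, str]]
    epp_betas: dict
    pairing_beta: float
    epp_design: pd.DataFrame | None = None  # realized, 2-SD scaled covariates + flag
    arrival_days: np.ndarray | None = None


@dataclass
class Colony:
    detections: pd.DataFrame
    individuals: pd.DataFrame
    breeding: pd.DataFrame
    boundary: object
    truth: GroundTruth
    config: ColonyConfig


def _grid_positions(n: int, extent: tuple, margin: float) -> np.ndarray:
    """n points on a centred rectangular grid inside the extent."""
    x0, y0, x1, y1 = extent
    margin = min(margin, 0.2 * min(x1 - x0, y1 - y0))
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    xs = np.linspace(x0 + margin, x1 - margin, ncol)
    ys = np.linspace(y0 + margin, y1 - margin, nrow)
    pts = np.array([(x, y) for y in ys for x in xs])[:n]
    return pts


def _event_starts(rng, k: int, day_seconds: int, min_gap: float, duration: float) -> np.ndarray:
    """k event start offsets with pairwise separation >= min_gap + duration."""
    step = min_gap + duration
    k = min(k, int(day_seconds // step) - 1)
    if k <= 0:
        return np.array([])
    slack = day_seconds - k * step
    starts = np.sort(rng.uniform(0, slack, k)) + np.arange(k) * step
    return starts


def simulate_colony(config: ColonyConfig) -> Colony:
    """Run the full generative model; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    x0, y0, x1, y1 = config.site_extent
    season_start = pd.Timestamp(config.season_start)
    n_days = config.n_days
    tags = [f"B{i + 1:03d}" for i in range(n)]
    sex = np.array(["F", "M"] * (n // 2 + 1))[:n]
    age = rng.choice(["yearling", "adult"], size=n)
    arrival = rng.integers(0, min(config.arrival_window_days, n_days), size=n)

    # tagging: ~70% before the study, the rest captured on their arrival day
    prestudy = rng.random(n) < 0.7
    tag_dates = np.where(
        prestudy,
        (pd.Timestamp("2017-06-01") + pd.to_timedelta(rng.integers(0, 60, n), unit="D")).strftime(
            "%Y-%m-%d"
        ),
        (season_start + pd.to_timedelta(arrival, unit="D")).strftime("%Y-%m-%d"),
    )
    individuals = pd.DataFrame(
        {"tag_id": tags, "sex": sex, "age_class": age, "tagging_date": tag_dates}
    )

    margin = min(30.0, 0.1 * min(x1 - x0, y1 - y0))
    homes = np.column_stack(
        [rng.uniform(x0 + margin, x1 - margin, n), rng.uniform(y0 + margin, y1 - margin, n)]
    )
    dist = np.sqrt(((homes[:, None, :] - homes[None, :, :]) ** 2).sum(-1))
    noise = rng.gamma(4.0, 0.25, size=(n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    affinity = np.exp(-dist / config.spatial_kernel_scale) * noise
    np.fill_diagonal(affinity, 0.0)
    affinity = affinity / affinity.max()

    # ------------------------------------------------------------------ pairing
    breeder = rng.random(n) > config.nonbreeder_fraction
    females = [i for i in range(n) if sex[i] == "F" and breeder[i]]
    males = [i for i in range(n) if sex[i] == "M" and breeder[i]]
    rng.shuffle(females)
    free = list(males)
    pairs: list[tuple[int, int]] = []
    for f in females:
        if not free:
            break
        # female-choice softmax on the affinity *percentile* among the
        # still-unpaired males: pairing_beta then acts on a 0-1 scale
        # regardless of the affinity magnitude distribution
        a = affinity[f, free]
        pct = (np.argsort(np.argsort(a)) + 0.5) / len(free)
        w = np.exp(config.pairing_beta * pct)
        m = free[rng.choice(len(free), p=w / w.sum())]
        free.remove(m)
        pairs.append((f, m))
    pairs.sort()

    # the pair bond itself strengthens association beyond shared space use:
    # mated birds travel and forage together, so their affinity is boosted
    # before any detections are generated
    for f, m in pairs:
        affinity[f, m] = affinity[m, f] = min(
            1.0, affinity[f, m] * config.pair_bond_boost
        )

    # ------------------------------------------------------------------ nests
    nest_xy = []
    for f, m in pairs:
        base = (homes[f] + homes[m]) / 2.0
        placed = False
        for attempt in range(200):
            jitter = config.nest_jitter * (1 + attempt / 50.0)
            pos = base + rng.normal(0, jitter, 2)
            pos = np.clip(pos, [x0 + 5, y0 + 5], [x1 - 5, y1 - 5])
            if all(
                np.hypot(*(pos - q)) >= config.min_nest_spacing for q in nest_xy
            ):
                nest_xy.append(pos)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "infeasible geometry: cannot place nests with minimum spacing"
            )
    settle_offsets = rng.integers(1, 31, size=len(pairs))
    breeding = pd.DataFrame(
        {
            "nest_id": [f"N{i + 1:03d}" for i in range(len(pairs))],
            "x": [p[0] for p in nest_xy],
            "y": [p[1] for p in nest_xy],
            "female_tag": [tags[f] for f, _ in pairs],
            "male_tag": [tags[m] for _, m in pairs],
            "settle_date": (
                pd.Timestamp(config.season_end) + pd.to_timedelta(settle_offsets, unit="D")
            ).strftime("%Y-%m-%d"),
            "replacement": False,
        }
    )

    # ------------------------------------------------------------- feeder stream
    feeder_pos = _grid_positions(config.n_feeders, config.site_extent, 40.0)
    feeder_ids = [f"F{i + 1:02d}" for i in range(config.n_feeders)]
    feeder_dist = np.sqrt(((feeder_pos[:, None, :] - homes[None, :, :]) ** 2).sum(-1))
    kernel_w = np.exp(-feeder_dist / config.spatial_kernel_scale)  # feeders x birds

    day_start_s = 7 * 3600  # daylight window 07:00-17:00
    day_len_s = 10 * 3600 - int(config.event_duration_seconds)
    epoch0 = season_start.value // 10**9

    det_time: list[int] = []
    det_loc: list[str] = []
    det_tag: list[int] = []
    mean_extra_members = max(config.mean_flock_size - 1.0, 0.0)
    for day in range(n_days):
        present = np.flatnonzero(arrival <= day)
        if present.size == 0:
            continue
        day_epoch = epoch0 + day * 86400 + day_start_s
        for fi in range(config.n_feeders):
            k = rng.poisson(config.events_per_feeder_day)
            starts = _event_starts(
                rng, k, day_len_s, config.min_event_gap_seconds, config.event_duration_seconds
            )
            if starts.size == 0:
                continue
            w_base = kernel_w[fi, present]
            for s in starts:
                size = min(1 + rng.poisson(mean_extra_members), present.size)
                members = [int(rng.choice(present.size, p=w_base / w_base.sum()))]
                avail = np.ones(present.size, dtype=bool)
                avail[members[0]] = False
                while len(members) < size:
                    boost = 1.0 + config.affinity_strength * affinity[
                        np.ix_(present, present[members])
                    ].mean(axis=1)
                    w = w_base * boost * avail
                    total = w.sum()
                    if total <= 0:
                        break
                    nxt = int(rng.choice(present.size, p=w / total))
                    members.append(nxt)
                    avail[nxt] = False
                for local in members:
                    bird = int(present[local])
                    n_det = 1 + rng.poisson(config.extra_detections_mean)
                    times = day_epoch + s + rng.uniform(
                        0, config.event_duration_seconds, n_det
                    )
                    for t in np.unique(times.astype(np.int64)):
                        det_time.append(int(t))
                        det_loc.append(feeder_ids[fi])
                        det_tag.append(bird)

    feeder_det = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(np.array(det_time, dtype="int64"), unit="s"),
            "location_id": det_loc,
            "tag_id": [tags[i] for i in det_tag],
            "location_type": "feeder",
        }
    )

    # --------------------------------------------------------------- box stream
    box_pos = _grid_positions(config.n_boxes, config.site_extent, 20.0)
    box_pos = box_pos + rng.uniform(-8, 8, size=box_pos.shape)
    box_ids = [f"X{i + 1:03d}" for i in range(config.n_boxes)]
    home_box = np.argmin(
        np.sqrt(((homes[:, None, :] - box_pos[None, :, :]) ** 2).sum(-1)), axis=1
    )

    rows_t: list[int] = []
    rows_loc: list[str] = []
    rows_tag: list[int] = []

    def add_visit(bird: int, bx: int, day: int, t_offset: float):
        rows_t.append(int(epoch0 + day * 86400 + day_start_s + t_offset))
        rows_loc.append(box_ids[bx])
        rows_tag.append(bird)

    for i in range(n):
        for _ in range(rng.poisson(config.solo_box_visits_mean)):
            day = int(rng.integers(arrival[i], n_days))
            add_visit(i, int(home_box[i]), day, rng.uniform(0, day_len_s))

    def joint_visit(a: int, b: int, bx: int):
        day = int(rng.integers(max(arrival[a], arrival[b]), n_days))
        t0 = rng.uniform(0, day_len_s - 60)
        add_visit(a, bx, day, t0)
        add_visit(b, bx, day, t0 + rng.uniform(1, 50))

    pair_of = {f: m for f, m in pairs}
    nest_box = {
        f: int(np.argmin(np.hypot(*(box_pos - nest_xy[k]).T)))
        for k, (f, m) in enumerate(pairs)
    }
    for f, m in pairs:
        if rng.random() < config.pair_coinspect_prob:
            for _ in range(1 + rng.poisson(1.0)):
                joint_visit(f, m, nest_box[f])
    breeding_males = np.array(males)
    for f, _ in pairs:
        for _ in range(rng.poisson(config.nonpair_coinspect_rate)):
            others = breeding_males[breeding_males != pair_of[f]]
            if others.size == 0:
                continue
            w = affinity[f, others] + 1e-9
            m = int(others[rng.choice(others.size, p=w / w.sum())])
            joint_visit(f, m, int(home_box[f]))

    box_det = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(np.array(rows_t, dtype="int64"), unit="s"),
            "location_id": rows_loc,
            "tag_id": [tags[i] for i in rows_tag],
            "location_type": "box",
        }
    )

    detections = io._finalize(
        pd.concat([feeder_det, box_det], ignore_index=True).drop_duplicates(
            subset=["timestamp", "location_id", "tag_id"]
        )
    )

    # ------------------------------------------------- realized EPP covariates
    truth = GroundTruth(
        affinity=affinity,
        home_centres=homes,
        tags=tags,
        social_pairs=[(tags[f], tags[m]) for f, m in pairs],
        epp_dyads=[],
        epp_betas=dict(config.epp_betas),
        pairing_beta=config.pairing_beta,
        arrival_days=arrival,
    )
    boundary = box(x0, y0, x1, y1)
    epp_design = _realized_epp_design(detections, individuals, breeding, boundary, config)
    if epp_design is not None and len(epp_design):
        logits = np.full(len(epp_design), config.epp_betas.get("intercept", 0.0))
        for key, col in [
            ("order", "z_order"),
            ("male_age", "z_male_age"),
            ("strength", "z_strength"),
            ("arrival_diff", "z_arrival_diff"),
            ("coinspection", "z_coinspect"),
        ]:
            beta = config.epp_betas.get(key, 0.0)
            if beta != 0.0:
                logits += beta * epp_design[col].to_numpy()
        p = 1.0 / (1.0 + np.exp(-logits))
        epp_design = epp_design.assign(epp=rng.random(len(p)) < p)
        truth.epp_dyads = [
            (r.female_tag, r.male_tag) for r in epp_design[epp_design["epp"]].itertuples()
        ]
    truth.epp_design = epp_design

    epp_by_female: dict[str, list[str]] = {}
    for f, m in truth.epp_dyads:
        epp_by_female.setdefault(f, []).append(m)
    breeding = breeding.assign(
        epp_partners=[";".join(sorted(epp_by_female.get(f, []))) for f in breeding["female_tag"]]
    )

    return Colony(
        detections=detections,
        individuals=individuals,
        breeding=breeding,
        boundary=boundary,
        truth=truth,
        config=config,
    )


def _realized_epp_design(detections, individuals, breeding, boundary, config):
    """Eligible-dyad table with realized, 2-SD-scaled covariates.

    Eligible: mixed-sex dyads where both members were detected during
    winter and both bred, excluding social pairs, with a finite
    neighbourhood order <= max_order.  Covariates are computed with the
    same analysis modules the pipeline uses (gap event detector).
    """
    resolved = geometry.resolve_breeding_records(breeding)
    if len(resolved) < 2:
        return None
    captures = io.capture_records_from_individuals(individuals, config.season_start)
    net = association.build_network(
        detections, capture_records=captures, season_start=config.season_start, detector="gap"
    )
    tmap = geometry.assign_territories(resolved, boundary)
    nest_ids, omat = geometry.order_matrix(tmap)
    nest_pos = {nid: i for i, nid in enumerate(nest_ids)}
    nest_of = {}
    for r in resolved.itertuples():
        nest_of[r.female_tag] = r.nest_id
        nest_of[r.male_tag] = r.nest_id

    meta = individuals.set_index("tag_id")
    present = set(net.ids)
    females = [t for t in resolved["female_tag"] if t in present]
    males = [t for t in resolved["male_tag"] if t in present]
    social = {tuple(sorted(p)) for p in zip(resolved["female_tag"], resolved["male_tag"])}

    arrivals = {}
    presence = io.presence_windows(detections, captures, season_start=config.season_start)
    for r in presence.itertuples():
        arrivals[r.tag_id] = (r.first_seen - pd.Timestamp(config.season_start)).days

    dyads = []
    for f in females:
        for m in males:
            if tuple(sorted((f, m))) in social:
                continue
            order = omat[nest_pos[nest_of[f]], nest_pos[nest_of[m]]]
            if not np.isfinite(order) or order > config.max_order:
                continue
            dyads.append((f, m, order))
    if not dyads:
        return None

    flags = coinspection.coinspection_flags(
        detections[detections["location_type"] == "box"],
        [(f, m) for f, m, _ in dyads],
        threshold_seconds=config.coinspection_threshold_seconds,
        cutoff_date=config.season_end,
    )
    flag_map = {(r.tag_a, r.tag_b): r.coinspect for r in flags.itertuples()}

    rows = []
    for f, m, order in dyads:
        rows.append(
            {
                "female_tag": f,
                "male_tag": m,
                "order": order,
                "male_age": 1.0 if meta.loc[m, "age_class"] == "adult" else 0.0,
                "strength": net.strength_of(f, m),
                "arrival_diff": abs(arrivals[f] - arrivals[m]),
                "coinspect": float(flag_map[(f, m)]),
            }
        )
    df = pd.DataFrame(rows)
    from .inference import scale_2sd

    for col in ["order", "male_age", "strength", "arrival_diff", "coinspect"]:
        z = "z_" + ("coinspect" if col == "coinspect" else col)
        try:
            df[z], _ = scale_2sd(df[col].to_numpy(), name=col)
        except ValueError:
            df[z] = 0.0
    return df


def write_colony(colony: Colony, outdir) -> dict:
    """Write the colony to plain-text files; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": outdir / "detections.csv",
        "individuals": outdir / "individuals.csv",
        "breeding": outdir / "breeding.csv",
        "boundary": outdir / "boundary.geojson",
        "truth": outdir / "truth.json",
    }
    io.write_detections(colony.detections, paths["detections"])
    colony.individuals.to_csv(paths["individuals"], index=False)
    colony.breeding.to_csv(paths["breeding"], index=False)
    with open(paths["boundary"], "w") as fh:
        json.dump(
            {"type": "Feature", "geometry": mapping(colony.boundary), "properties": {}}, fh
        )
    t = colony.truth
    payload = {
        "tags": t.tags,
        "social_pairs": t.social_pairs,
        "epp_dyads": t.epp_dyads,
        "epp_betas": t.epp_betas,
        "pairing_beta": t.pairing_beta,
        "home_centres": t.home_centres.tolist(),
        "arrival_days": t.arrival_days.tolist() if t.arrival_days is not None else None,
        "affinity": t.affinity.tolist(),
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(colony.config).items()},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh)
    return paths


def simulate_dyad_table(
    n_dyads: int = 1500,
    betas: dict | None = None,
    seed: int = 0,
    strength_by_order: bool = True,
) -> pd.DataFrame:
    """Dyad-level generator for calibration studies of the inference stage.

    Emulates the eligible-dyad table of a ~120-bird colony without the
    detection layer: neighbourhood orders follow a plausible frequency
    profile, winter association strength declines with order when
    ``strength_by_order`` (so the restricted permutation has real strata
    structure), and the binary response is drawn from ``betas`` applied to
    the 2-SD-scaled covariates.  With the strength coefficient at zero the
    response is conditionally independent of strength given order.
    """
    rng = np.random.default_rng(seed)
    betas = dict(DEFAULT_EPP_BETAS) if betas is None else betas
    order = rng.choice([1, 2, 3, 4, 5], size=n_dyads, p=[0.12, 0.2, 0.24, 0.24, 0.2])
    if strength_by_order:
        mu = 0.78 - 0.09 * order
    else:
        mu = np.full(n_dyads, 0.5)
    strength = np.clip(rng.normal(mu, 0.22), 0.0, 1.0)
    male_age = (rng.random(n_dyads) < 0.5).astype(float)
    arrival_diff = rng.integers(0, 60, n_dyads).astype(float)
    coinspect = (rng.random(n_dyads) < 0.1).astype(float)

    df = pd.DataFrame(
        {
            "order": order.astype(float),
            "strength": strength,
            "male_age": male_age,
            "arrival_diff": arrival_diff,
            "coinspect": coinspect,
            "social_pair": False,
        }
    )
    from .inference import scale_2sd

    logits = np.full(n_dyads, betas.get("intercept", 0.0))
    for key, col in [
        ("order", "order"),
        ("male_age", "male_age"),
        ("strength", "strength"),
        ("arrival_diff", "arrival_diff"),
        ("coinspection", "coinspect"),
    ]:
        z, _ = scale_2sd(df[col].to_numpy(), name=col)
        df["z_" + col] = z
        logits += betas.get(key, 0.0) * z
    df["epp"] = rng.random(n_dyads) < 1.0 / (1.0 + np.exp(-logits))
    return df
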