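"""End-to-end analysis pipeline from raw colony files to result tables.

The pipeline assembles a single *dyad table* — one row per mixed-sex dyad
in which both birds were present during winter and later bred in the study
site — carrying the winter association strength, spatial foraging overlap,
neighbourhood order, male age, arrival-date difference, co-inspection flag
and the two outcomes (social pair, extra-pair paternity).  Five analyses
run over that table:

1. social-pair logistic regression (strength only, within-order null),
2. breeding-proximity linear regression (strength + overlap, 2-SD scaled,
   last-feeder node-permutation null) with the neighbourhood-order mean
   comparison,
3. EPP logistic regression (five 2-SD-scaled covariates, within-order
   null), with optional close-neighbourhood and subset reruns,
4. four-category association-strength comparison,
5. temporal reruns on monthly and early/late-winter networks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape

from . import association, coinspection, geometry, inference, io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    season_start: str = "2017-11-01"
    season_end: str = "2018-03-14"
    nest_building_cutoff: str = "2018-03-14"
    detector: str = "gap"
    gap_seconds: float = 600.0
    gmm_max_components: int = 20
    gmm_min_detections: int = 2
    coinspection_threshold_seconds: float = 60.0
    max_order: int = 5
    n_perm: int = 1000
    temporal_n_perm: int | None = None  # defaults to n_perm
    seed: int = 0
    close_neighbourhood: bool = False
    subset: str | None = None  # None | "prestudy" | "bred2017" | "newcomer"
    presence_from: str = "both"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.subset not in (None, "prestudy", "bred2017", "newcomer"):
            raise ValueError(f"unknown subset {self.subset!r}")


@dataclass
class ColonyData:
    """Raw inputs of one study season."""

    detections: pd.DataFrame
    individuals: pd.DataFrame
    breeding: pd.DataFrame
    boundary: object


def load_colony(indir) -> ColonyData:
    """Load a colony directory written by :func:`flocknet.synthetic.write_colony`."""
    indir = Path(indir)
    stream = io.read_detections(indir / "detections.csv")
    if stream.n_rejected:
        logger.warning("%d detection rows rejected on load", stream.n_rejected)
    with open(indir / "boundary.geojson") as fh:
        boundary = shape(json.load(fh)["geometry"])
    return ColonyData(
        detections=stream.data,
        individuals=pd.read_csv(indir / "individuals.csv"),
        breeding=pd.read_csv(indir / "breeding.csv"),
        boundary=boundary,
    )


def colony_data(colony) -> ColonyData:
    """Adapter from an in-memory synthetic colony."""
    return ColonyData(
        detections=colony.detections,
        individuals=colony.individuals,
        breeding=colony.breeding,
        boundary=colony.boundary,
    )


# ---------------------------------------------------------------------------
# Dyad table assembly


@dataclass
class PipelineContext:
    """Shared intermediate products cached across analyses."""

    dyads: pd.DataFrame
    network: association.AssociationMatrix
    last_feeder: dict
    resolved_breeding: pd.DataFrame
    territory_map: geometry.TerritoryMap
    counts: dict = field(default_factory=dict)


def _parse_epp_partners(breeding: pd.DataFrame) -> set[tuple[str, str]]:
    out = set()
    if "epp_partners" not in breeding.columns:
        return out
    for r in breeding.itertuples():
        partners = str(getattr(r, "epp_partners", "") or "")
        for m in partners.split(";"):
            if m:
                out.add((r.female_tag, m))
    return out


def build_context(data: ColonyData, config: RunConfig) -> PipelineContext:
    """Run all upstream stages and assemble the dyad table."""
    captures = io.capture_records_from_individuals(data.individuals, config.season_start)
    net = association.build_network(
        data.detections,
        capture_records=captures,
        season_start=config.season_start,
        detector=config.detector,
        gap_seconds=config.gap_seconds,
        gmm_max_components=config.gmm_max_components,
        gmm_min_detections=config.gmm_min_detections,
        seed=config.seed,
        presence_from=config.presence_from,
    )
    feeder_df = data.detections[data.detections["location_type"] == "feeder"]
    ov_ids, ov_mat = association.spatial_overlap(feeder_df, ids=net.ids)
    lf = association.last_feeder(feeder_df).to_dict()
    last_feeder_map = {t: lf.get(t, f"none:{t}") for t in net.ids}

    resolved = geometry.resolve_breeding_records(data.breeding)
    tmap = geometry.assign_territories(resolved, data.boundary)
    nest_ids, omat = geometry.order_matrix(tmap)
    nest_pos = {nid: i for i, nid in enumerate(nest_ids)}
    nest_of = {}
    for r in resolved.itertuples():
        nest_of[r.female_tag] = r.nest_id
        nest_of[r.male_tag] = r.nest_id

    meta = data.individuals.set_index("tag_id")
    present = set(net.ids)
    idx = {t: i for i, t in enumerate(net.ids)}
    females = sorted(t for t in resolved["female_tag"] if t in present)
    males = sorted(t for t in resolved["male_tag"] if t in present)
    social = {tuple(sorted(p)) for p in zip(resolved["female_tag"], resolved["male_tag"])}
    epp_set = _parse_epp_partners(data.breeding)

    presence = io.presence_windows(
        data.detections, captures, season_start=config.season_start
    ).set_index("tag_id")
    season_start = pd.Timestamp(config.season_start)

    dyad_keys = [(f, m) for f in females for m in males]
    flags = coinspection.coinspection_flags(
        data.detections[data.detections["location_type"] == "box"],
        dyad_keys,
        threshold_seconds=config.coinspection_threshold_seconds,
        cutoff_date=config.nest_building_cutoff,
    )
    flag_map = {(r.tag_a, r.tag_b): bool(r.coinspect) for r in flags.itertuples()}

    rows = []
    for f, m in dyad_keys:
        fi, mi = idx[f], idx[m]
        order = omat[nest_pos[nest_of[f]], nest_pos[nest_of[m]]]
        rows.append(
            {
                "female_tag": f,
                "male_tag": m,
                "strength": float(net.strength[fi, mi]),
                "overlap": float(ov_mat[fi, mi]),
                "order": float(order),
                "male_age": 1.0 if meta.loc[m, "age_class"] == "adult" else 0.0,
                "arrival_diff": float(
                    abs(
                        (presence.loc[f, "first_seen"] - season_start).days
                        - (presence.loc[m, "first_seen"] - season_start).days
                    )
                ),
                "coinspect": bool(flag_map[(f, m)]),
                "social_pair": tuple(sorted((f, m))) in social,
                "epp": (f, m) in epp_set,
                "prestudy": bool(
                    pd.Timestamp(meta.loc[f, "tagging_date"]) < season_start
                    and pd.Timestamp(meta.loc[m, "tagging_date"]) < season_start
                ),
            }
        )
    dyads = pd.DataFrame(rows)
    if "bred_2017" in meta.columns:
        b17 = meta["bred_2017"].astype(bool)
        dyads["bred2017"] = [
            bool(b17.get(f, False) and b17.get(m, False))
            for f, m in zip(dyads["female_tag"], dyads["male_tag"])
        ]
        dyads["newcomer"] = [
            not (b17.get(f, False) and b17.get(m, False))
            for f, m in zip(dyads["female_tag"], dyads["male_tag"])
        ]
    ctx = PipelineContext(
        dyads=dyads,
        network=net,
        last_feeder=last_feeder_map,
        resolved_breeding=resolved,
        territory_map=tmap,
    )
    ctx.counts = {
        "individuals_winter": len(net.ids),
        "social_pairs": len(resolved),
        "dyads": len(dyads),
        "epp_dyads": int(dyads["epp"].sum()),
    }
    return ctx


def _apply_subset(dyads: pd.DataFrame, subset: str | None) -> pd.DataFrame:
    if subset is None:
        return dyads
    if subset not in dyads.columns:
        raise ValueError(f"subset column {subset!r} not available in the dyad table")
    return dyads[dyads[subset].astype(bool)]


# ---------------------------------------------------------------------------
# Analyses


def run_social_pair_analysis(ctx: PipelineContext, config: RunConfig) -> pd.DataFrame:
    """Does winter association strength predict social pairing?

    Logistic dyadic regression of the social-pair flag on strength over
    all eligible mixed-sex dyads; null model shuffles strength within
    neighbourhood-order strata, pooling social pairs with order-1 dyads.
    """
    tab = _apply_subset(ctx.dyads, config.subset).reset_index(drop=True)
    if tab["social_pair"].sum() == 0:
        raise RuntimeError("no social pairs in the dyad table")
    y = tab["social_pair"].to_numpy(dtype=float)

    def null_draw(rng):
        perm = inference.permute_strength_within_order(tab, rng)
        return perm[["strength"]].to_numpy()

    return inference.permutation_test(
        y,
        tab[["strength"]].to_numpy(),
        ["strength"],
        null_draw,
        n_perm=config.n_perm,
        seed=config.seed + 11,
        family="logistic",
    )


def run_proximity_analysis(
    ctx: PipelineContext, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Does association strength predict breeding proximity?

    Linear dyadic regression of neighbourhood order (1..max_order, social
    pairs excluded) on 2-SD-scaled strength and spatial overlap.  The null
    reassigns network positions among birds that were last recorded at the
    same feeder, holding everything spatial fixed.  Also returns the
    pairwise mean-strength comparison across orders.
    """
    tab = _apply_subset(ctx.dyads, config.subset)
    tab = tab[
        ~tab["social_pair"]
        & tab["order"].notna()
        & (tab["order"] >= 1)
        & (tab["order"] <= config.max_order)
    ].reset_index(drop=True)
    if len(tab) < 10:
        raise RuntimeError("too few dyads for the proximity analysis")
    y = tab["order"].to_numpy(dtype=float)
    z_strength, s_div = inference.scale_2sd(tab["strength"].to_numpy(), "strength")
    z_overlap, _ = inference.scale_2sd(tab["overlap"].to_numpy(), "overlap")
    X = np.column_stack([z_strength, z_overlap])

    net = ctx.network
    fi = tab["female_tag"].map(net.ids.index).to_numpy()
    mi = tab["male_tag"].map(net.ids.index).to_numpy()

    def null_draw(rng):
        pmat = inference.permute_nodes_by_last_feeder(
            net.ids, net.strength, ctx.last_feeder, rng
        )
        return np.column_stack([pmat[fi, mi] / s_div, z_overlap])

    reg = inference.permutation_test(
        y,
        X,
        ["strength", "overlap"],
        null_draw,
        n_perm=config.n_perm,
        seed=config.seed + 23,
        family="linear",
    )
    order_cmp = inference.category_mean_test(
        tab["strength"].to_numpy(),
        tab["order"].astype(int).to_numpy(),
        n_perm=config.n_perm,
        seed=config.seed + 29,
    )
    return reg, order_cmp


EPP_COVARIATES = ["order", "male_age", "strength", "arrival_diff", "coinspect"]


def epp_design(ctx: PipelineContext, config: RunConfig) -> pd.DataFrame:
    """Eligible-dyad table for the EPP model, with 2-SD-scaled covariates."""
    max_order = 2 if config.close_neighbourhood else config.max_order
    tab = _apply_subset(ctx.dyads, config.subset)
    tab = tab[
        ~tab["social_pair"]
        & tab["order"].notna()
        & (tab["order"] >= 1)
        & (tab["order"] <= max_order)
    ].reset_index(drop=True)
    for col in EPP_COVARIATES:
        tab["z_" + col], _ = inference.scale_2sd(
            tab[col].to_numpy(dtype=float), name=col
        )
    return tab


def run_epp_analysis(ctx: PipelineContext, config: RunConfig) -> pd.DataFrame:
    """Does winter behaviour predict which dyads have extra-pair young?

    Logistic dyadic regression of the EPP flag on neighbourhood order,
    male age, winter association strength, arrival-date difference and
    co-inspection (all 2-SD scaled); within-order strength permutation
    null.  Output mirrors a published-table layout: estimate, exp(b),
    empirical p and the 95% null range per term.
    """
    tab = epp_design(ctx, config)
    if tab["epp"].sum() == 0:
        raise RuntimeError("no EPP dyads in the design")
    y = tab["epp"].to_numpy(dtype=float)
    zcols = ["z_" + c for c in EPP_COVARIATES]
    X = tab[zcols].to_numpy()
    strength_col = zcols.index("z_strength")

    perm_tab = tab[["order", "social_pair"]].assign(strength=tab["z_strength"])

    def null_draw(rng):
        perm = inference.permute_strength_within_order(perm_tab, rng)
        Xp = X.copy()
        Xp[:, strength_col] = perm["strength"].to_numpy()
        return Xp

    return inference.permutation_test(
        y,
        X,
        EPP_COVARIATES,
        null_draw,
        n_perm=config.n_perm,
        seed=config.seed + 37,
        family="logistic",
    )


def run_category_comparison(ctx: PipelineContext, config: RunConfig) -> pd.DataFrame:
    """Compare mean strength between social pairs, extra-pair partners,
    direct neighbours and second-order neighbours.

    A dyad that is both an extra-pair partnership and an order-1
    neighbour counts as extra-pair partner.
    """
    tab = _apply_subset(ctx.dyads, config.subset)
    labels = np.where(
        tab["social_pair"],
        "social_pair",
        np.where(
            tab["epp"],
            "epp_partner",
            np.where(tab["order"] == 1, "order_1", np.where(tab["order"] == 2, "order_2", "")),
        ),
    )
    keep = labels != ""
    return inference.category_mean_test(
        tab.loc[keep, "strength"].to_numpy(),
        labels[keep],
        n_perm=config.n_perm,
        seed=config.seed + 41,
    )


def season_windows(config: RunConfig) -> dict[str, tuple[str, str]]:
    """Monthly plus early/late-winter analysis windows inside the season."""
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end) - pd.Timedelta(days=1)
    windows: dict[str, tuple[str, str]] = {}
    cur = start.normalize().replace(day=1)
    while cur <= end:
        nxt = (cur + pd.offsets.MonthBegin(1)) - pd.Timedelta(days=1)
        w0, w1 = max(cur, start), min(nxt, end)
        windows[cur.strftime("%Y-%m")] = (str(w0.date()), str(w1.date()))
        cur = cur + pd.offsets.MonthBegin(1)
    jan_end = min(pd.Timestamp("2018-01-31"), end)
    feb_start = pd.Timestamp("2018-02-01")
    if start.year != 2017:  # generic seasons: split at the 3rd month boundary
        months = sorted(windows)
        cutpoint = len(months) * 3 // 5 or 1
        jan_end = pd.Timestamp(windows[months[cutpoint - 1]][1])
        feb_start = jan_end + pd.Timedelta(days=1)
    windows["early"] = (str(start.date()), str(jan_end.date()))
    if feb_start <= end:
        windows["late"] = (str(feb_start.date()), str(end.date()))
    return windows


def run_temporal_analysis(
    data: ColonyData, ctx: PipelineContext, config: RunConfig
) -> pd.DataFrame:
    """Re-estimate the social-pair and EPP strength effects per time window.

    The association network (and hence the strength covariate) is rebuilt
    from detections inside each monthly / early / late window; all other
    covariates and the outcomes stay at their full-season values.  Windows
    with too few informative dyads are skipped with a logged reason.
    """
    captures = io.capture_records_from_individuals(data.individuals, config.season_start)
    n_perm = config.temporal_n_perm or config.n_perm
    rows = []
    for name, (w0, w1) in season_windows(config).items():
        net_w = association.build_network(
            data.detections,
            capture_records=captures,
            window=(w0, w1),
            detector=config.detector,
            gap_seconds=config.gap_seconds,
            gmm_max_components=config.gmm_max_components,
            gmm_min_detections=config.gmm_min_detections,
            seed=config.seed,
            presence_from=config.presence_from,
            label=name,
        )
        idx = {t: i for i, t in enumerate(net_w.ids)}
        dy = ctx.dyads.copy()
        in_win = dy["female_tag"].isin(idx) & dy["male_tag"].isin(idx)
        dy = dy[in_win].reset_index(drop=True)
        if len(dy) < 10:
            logger.warning("window %s skipped: %d dyads", name, len(dy))
            continue
        dy["strength"] = [
            net_w.strength[idx[f], idx[m]]
            for f, m in zip(dy["female_tag"], dy["male_tag"])
        ]
        sub_ctx = dataclasses.replace(ctx, dyads=dy)
        sub_cfg = dataclasses.replace(config, n_perm=n_perm)
        for analysis, runner in (
            ("social_pair", run_social_pair_analysis),
            ("epp", run_epp_analysis),
        ):
            try:
                res = runner(sub_ctx, sub_cfg)
            except (RuntimeError, ValueError) as exc:
                logger.warning("window %s %s skipped: %s", name, analysis, exc)
                continue
            res = res[res["term"] == "strength"]
            for r in res.itertuples():
                rows.append(
                    {
                        "window": name,
                        "window_start": w0,
                        "window_end": w1,
                        "analysis": analysis,
                        "estimate": r.estimate,
                        "p_empirical": r.p_empirical,
                        "significant": r.significant,
                        "n_dyads": len(dy),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration


def run_all(data: ColonyData, config: RunConfig) -> dict:
    """Run every analysis; returns a report of result tables and counts."""
    ctx = build_context(data, config)
    report: dict = {
        "config": dataclasses.asdict(config),
        "counts": ctx.counts,
        "tables": {},
        "skipped": {},
    }
    runners = {
        "social_pair": lambda: run_social_pair_analysis(ctx, config),
        "proximity": lambda: run_proximity_analysis(ctx, config)[0],
        "order_means": lambda: run_proximity_analysis(ctx, config)[1],
        "epp": lambda: run_epp_analysis(ctx, config),
        "categories": lambda: run_category_comparison(ctx, config),
        "temporal": lambda: run_temporal_analysis(data, ctx, config),
    }
    prox_cache: tuple | None = None
    for name in ["social_pair", "proximity", "order_means", "epp", "categories", "temporal"]:
        try:
            if name == "proximity":
                prox_cache = run_proximity_analysis(ctx, config)
                report["tables"][name] = prox_cache[0]
            elif name == "order_means":
                if prox_cache is None:
                    prox_cache = run_proximity_analysis(ctx, config)
                report["tables"][name] = prox_cache[1]
            else:
                report["tables"][name] = runners[name]()
        except (RuntimeError, ValueError) as exc:
            logger.warning("analysis %s skipped: %s", name, exc)
            report["skipped"][name] = str(exc)
    return report


def write_report(report: dict, outdir) -> None:
    """Write result tables as CSV plus a JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {k: v for k, v in report.items() if k != "tables"}
    for name, table in report["tables"].items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
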