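"""Shared fixtures: synthetic colonies at test scale.

The heavy fixtures are session-scoped so the planted-effect colonies are
simulated once and shared between the recovery, gradient and invariant
tests.  Colony sizes are scaled down from the package defaults (90 birds,
12 feeders, 92-day season for the replicate study; 60 birds, 10 feeders,
70 days for the single-colony pipeline tests) to keep the suite fast; the
planted effect sizes are the package defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flocknet import pipeline, synthetic

STUDY_SEEDS = list(range(100, 120))
STUDY_COLONY_KWARGS = dict(
    n_individuals=90,
    n_feeders=12,
    n_boxes=50,
    season_end="2018-02-01",
    events_per_feeder_day=8.0,
)
STUDY_RUN_KWARGS = dict(
    season_end="2018-02-01", nest_building_cutoff="2018-02-01", n_perm=200
)


def make_stream(rows):
    """Detection DataFrame from (timestamp, location, tag, type) tuples."""
    df = pd.DataFrame(rows, columns=["timestamp", "location_id", "tag_id", "location_type"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    return df


@pytest.fixture(scope="session")
def small_colony():
    cfg = synthetic.ColonyConfig(
        n_individuals=60,
        n_feeders=10,
        n_boxes=40,
        season_end="2018-01-10",
        events_per_feeder_day=6.0,
        seed=7,
    )
    return synthetic.simulate_colony(cfg)


@pytest.fixture(scope="session")
def small_run_config():
    return pipeline.RunConfig(
        season_end="2018-01-10", nest_building_cutoff="2018-01-10", n_perm=60, seed=7
    )


@pytest.fixture(scope="session")
def small_context(small_colony, small_run_config):
    return pipeline.build_context(pipeline.colony_data(small_colony), small_run_config)


@pytest.fixture(scope="session")
def study_replicates():
    """Twenty planted-effect colonies with their fitted analyses.

    Per replicate: the dyad table, the social-pair and EPP permutation
    results, and summary statistics used by the recovery, gradient and
    planted-structure tests.
    """
    out = []
    for seed in STUDY_SEEDS:
        cfg = synthetic.ColonyConfig(seed=seed, **STUDY_COLONY_KWARGS)
        colony = synthetic.simulate_colony(cfg)
        rc = pipeline.RunConfig(seed=seed, **STUDY_RUN_KWARGS)
        ctx = pipeline.build_context(pipeline.colony_data(colony), rc)
        pair = pipeline.run_social_pair_analysis(ctx, rc)
        epp = pipeline.run_epp_analysis(ctx, rc).set_index("term")

        net = ctx.network
        idx = {t: i for i, t in enumerate(net.ids)}
        pair_sri = [
            net.sri[idx[f], idx[m]]
            for f, m in colony.truth.social_pairs
            if f in idx and m in idx
        ]
        offdiag = net.sri[~np.eye(len(net.ids), dtype=bool)]
        out.append(
            {
                "seed": seed,
                "dyads": ctx.dyads,
                "truth": colony.truth,
                "pair_result": pair.set_index("term"),
                "epp_result": epp,
                "pair_sri_mean": float(np.mean(pair_sri)),
                "population_sri_mean": float(offdiag.mean()),
            }
        )
    return out
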