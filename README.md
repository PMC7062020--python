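# flocknet

Winter foraging associations in cavity-nesting songbird colonies carry over
into spring mating decisions: birds that flock together tend to nest closer
together, and female–male dyads with stronger winter associations are more
likely to end up as social pairs — and, beyond what spatial proximity alone
predicts, to have extra-pair young together.  `flocknet` implements the full
inference chain needed to test these hypotheses from raw RFID (PIT-tag)
detection streams, for behavioural ecologists working with feeder/nest-box
colony systems:

1. **Detection streams → flocking events.**  Per-location, per-day detection
   sequences are segmented into gathering events, either with a BIC-selected
   1-D Gaussian mixture (hard assignment, deterministic under a fixed seed)
   or with a transparent quiet-gap rule that doubles as its independent
   check.
2. **Events → association network.**  Dyadic co-occurrence is scored with
   the simple ratio index

   *S<sub>AB</sub>* = *x* / (*x* + *y<sub>AB</sub>* + *y<sub>A</sub>* + *y<sub>B</sub>*),

   where *x* counts events with both birds, *y<sub>A</sub>* (*y<sub>B</sub>*)
   events with one but not the other while both were known present, and
   *y<sub>AB</sub>* simultaneous events at different feeders.  Each focal
   bird's associates are then ranked by SRI, ranks are rescaled to [0, 1],
   and the mean of the two directed values is the dyadic **winter
   association strength**.  Spatial foraging overlap is the summed minimum
   of the two birds' feeder-use distributions.
3. **Breeding geometry.**  Nests become Thiessen (Voronoi) territories
   clipped to the site boundary; the **neighbourhood order** of a dyad is
   the graph distance in the shared-border adjacency graph (order 1 =
   bordering territories).  Polygyny (keep the first-settled female) and
   replacement-clutch rules are applied first.
4. **Nest-box co-inspection.**  A mixed-sex dyad "inspected a box together"
   if both members were detected at one box on one day within 60 s
   (calibratable), before nest building began.
5. **Dyadic inference.**  Logistic/linear regressions on the dyad table
   (social pairing, breeding proximity, extra-pair paternity) with
   MRQAP-style significance from restricted permutations: association
   strengths shuffled within neighbourhood-order strata, or whole network
   positions swapped among birds sharing their last winter feeder.
   Two-sided empirical p-values are reported alongside the
   outside-95%-null-range rule; continuous and binary covariates are made
   comparable by 2-SD scaling.

Because raw field datasets of this kind are rarely public, the package
ships a first-class synthetic colony generator (`flocknet.synthetic`) with
planted, recoverable effects — latent affinity drives flock membership,
pairing and nest placement, and extra-pair paternity is drawn from a known
logistic model on the *realized* dyadic covariates, so simulation studies
can compare fitted coefficients against exact generating values.

## Worked example

```python
from flocknet import pipeline, synthetic

cfg = synthetic.ColonyConfig(n_individuals=90, n_feeders=12, n_boxes=50,
                             season_end="2018-02-01",
                             events_per_feeder_day=8.0, seed=42)
colony = synthetic.simulate_colony(cfg)

rc = pipeline.RunConfig(season_end="2018-02-01",
                        nest_building_cutoff="2018-02-01",
                        n_perm=1000, seed=42)
ctx = pipeline.build_context(pipeline.colony_data(colony), rc)
print(ctx.counts)
print(pipeline.run_epp_analysis(ctx, rc))
```

prints (abridged):

```
{'individuals_winter': 90, 'social_pairs': 36, 'dyads': 1296, 'epp_dyads': 115}
        term  estimate  exp_estimate  p_empirical  significant
   intercept    -2.097         0.123        0.001         True
       order    -2.444         0.087        1.000         True
    male_age     1.063         2.895        0.017         True
    strength     1.322         3.750        0.001         True
arrival_diff    -0.046         0.955        1.000         True
   coinspect     0.226         1.253        1.000         True
```

The `strength` row is the quantity of interest: the planted association →
EPP effect (+1.0 on the 2-SD scale in this colony) is recovered at 1.32
with empirical p = 0.001 from 1000 within-order permutations — dyads that
associated more during winter are ~3.8× more likely per 2 SD of strength to
have extra-pair young.  The `order` estimate (−2.44, planted −2.48) says
EPP falls off steeply with breeding distance.  Only the `strength` row's
permutation inference is meaningful here: the null model shuffles the
association pattern while everything spatial stays fixed, so p-values and
range flags for the other rows are reported for completeness, not for
testing.  The same context powers the remaining analyses
(`run_social_pair_analysis`, `run_proximity_analysis`,
`run_category_comparison`, `run_temporal_analysis`), and the planted
strength-by-order gradient comes out monotone (mean strength 0.66, 0.57,
0.50, 0.41, 0.31 for orders 1–5).

A CLI wraps the same functions:

```bash
flocknet simulate --seed 42 --out colony/
flocknet analyse --data colony/ --seed 42 --n-perm 1000 --out results/
```

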