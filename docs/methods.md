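# Methods

This note documents the models and procedures implemented in `flocknet`,
the assumptions behind them, the tunable parameters that matter, and what
the synthetic-colony validation does and does not establish.

## From detections to flocking events

The raw observable is an antenna read: (timestamp, location, tag).  Birds
feed in bursts, so the per-location, per-day time series is segmented into
gathering events.

**Mixture detector** (`events.detect_events_gmm`).  For each location-day,
1-D Gaussian mixtures with K = 1..min(`max_components`, n) components are
fit to the detection times; K is chosen by BIC and detections are
hard-assigned to their maximum-responsibility component.  Determinism is
enforced by quantile-spaced mean initialization, a fixed random seed, and
breaking responsibility ties toward the earlier component.  Two numerical
choices matter:

* `reg_covar = 1 s²` stops components collapsing onto duplicate
  timestamps.
* A burst of detections is roughly uniform in time, and a uniform block is
  cheaper for a Gaussian mixture to encode as several narrow components
  than as one wide one, so raw BIC over-splits. Components are therefore
  merged when the gap between them is at most `merge_factor` (default 10)
  times the location-day's median positive inter-detection gap — a robust
  estimate of within-burst spacing.  Genuine bursts are separated by far
  more than that.  `merge_factor = 0` disables the merge.

**Gap detector** (`events.detect_events_gap`).  Split wherever consecutive
detections are more than `gap_seconds` (default 600 s) apart.  On bursts
separated by ≥ 10× the within-burst spacing the two detectors produce
identical partitions (a tested property); they differ only on overlapping
gatherings, where no ground truth exists.  The pipeline default is the gap
detector (deterministic, O(n log n), no fitted model); the mixture
detector is a config switch.  Faithfully resolving *overlapping* bursts is
a non-goal.

## Association indices

For a dyad (A, B): S_AB = x / (x + y_AB + y_A + y_B), with counts defined
over the period both birds were known present (first evidence — detection
or in-season capture, clipped to the season start — to last detection;
a single contiguous window).  "Detected at the same time but not
together" (y_AB) is operationalized as two time-overlapping events at
*different* locations, one containing each bird without the other; the
required span overlap is configurable (default: any positive overlap).
An empty denominator (never co-present, or no events) defines S_AB = 0
with a flag rather than NaN.

Raw SRI distributions differ between focal birds (a bird visiting busy
feeders accumulates many low indices), so the dyadic statistic used by
every analysis is the **ranked transform**: each focal's associates are
ranked by SRI ascending (ties get average ranks), ranks are shifted to
start at zero and divided by their maximum, and the dyadic *winter
association strength* is the mean of the two directed values.  Two edge
conventions: a sole associate gets directed value 1 (it is trivially the
strongest), and all other network members count as associates, including
never-associated ones at SRI 0 — both choices are visible in the printed
worked example the implementation reproduces (associate SRIs 0/0.5/1 →
ranks 1/2/3 → values 0/0.5/1, divisor 2).

**Spatial overlap** is Σ_l min(p_A(l), p_B(l)) over feeders, where p_i is
bird i's detection-count distribution across feeders (counts proxy time
spent).  **Windowed networks** (months; early winter Nov–Jan; late winter
Feb 1–Mar 14) recompute presence, events and both indices from the
detections inside the window only.

## Breeding geometry

Brood records are first reduced to social pairs: replacement clutches are
dropped and a polygynous male keeps only his first-settled female (ties
break to the lower nest id, with a warning).  Nests then get Thiessen
(Voronoi) territories clipped to the site boundary — implemented by
mirroring nest points across the bounding-box sides so every cell is
finite, then intersecting with the boundary polygon.  Adjacency requires a
shared border of positive length (> 1e-9 m): cells meeting at a point are
a tessellation artefact, not neighbours.  Neighbourhood order is the
shortest-path distance in this adjacency graph, computed over *all*
breeding pairs regardless of winter presence; analysis dyads are filtered
afterwards (default orders 1–5).  Coordinates are planar metres.

## Nest-box co-inspection

A mixed-sex dyad co-inspected a box if, on some day at some box strictly
before the nest-building cutoff, both members were detected within
`threshold_seconds`.  The threshold comparison is inclusive (≤ 60 s, i.e.
"within one minute") and the cutoff exclusive (the first nest-building day
no longer counts as winter).  Raw reads are differenced directly, without
bout aggregation.  `calibrate_threshold` reproduces the calibration
procedure: the distribution of per-day, per-box minimum time differences
between future social mates.

## Dyadic inference

Point estimation is ordinary MLE/OLS on the vectorized dyad table —
logistic regression by IRLS (log-likelihood tolerance 1e-8, with
step-halving; separation is flagged and switches the permutation statistic
to the intercept-only score statistic), linear regression by least squares
with an explicit rank check.  The "matrix regression" character lives
entirely in the inference: coefficients are re-estimated on permuted data
and significance is judged against that null distribution, never against
asymptotic standard errors.

* **Within-order strength permutation** — association strengths are
  shuffled among dyads of the same neighbourhood order; social pairs are
  pooled with the order-1 stratum.  This preserves the spatial breeding
  structure exactly and randomizes only who-associated-with-whom.
* **Last-feeder node permutation** — whole network positions (rows and
  columns of the strength matrix) are swapped among birds whose last
  winter feeder was the same; identity-linked covariates stay put.  This
  separates social preference from shared space use.
* **Label shuffles** for category-mean comparisons (the four relationship
  categories, or the five neighbourhood orders).

Empirical two-sided p = (1 + #{|b*| ≥ |b_obs|}) / (n_perm + 1), reported
with the central 95% null range and the outside-range flag; default
n_perm = 1000.  Only the shuffled quantity's inference is interpretable:
the null distribution of a *non-permuted* covariate's coefficient varies
only through refit coupling, so its band is nearly degenerate and its
flag should be ignored (the permutation schemes deliberately randomize
one pattern at a time).  Covariates are scaled by 2·SD (ddof = 1) so
binary and continuous effect sizes are comparable.  In the
extra-pair-paternity (EPP) model the dyad universe is: mixed-sex, both
winter-present, both bred, social pairs excluded, order 1–5 (1–2 in the
close-neighbourhood rerun); subset reruns (pre-study-tagged birds,
previous-season breeders, newcomer dyads) are row filters applied before
fitting.

## Synthetic colony

The generator plants known structure so every stage is testable without
field data.  Mechanisms, in order:

1. Home centres uniform over a rectangular site (default 640 × 625 m ≈ 40
   ha); latent affinity a_ij = exp(−d_ij / `spatial_kernel_scale`) ×
   gamma noise, symmetric, zero diagonal, scaled to max 1.
2. Social pairs form by female choice: a softmax (weight exp(`pairing_beta`
   × affinity percentile)) over still-unpaired males.  The pair bond then
   *boosts* the pair's affinity (default ×3, capped at 1) — mates travel
   together beyond what shared space predicts; without this, social pairs
   would be statistically indistinguishable from other first-order dyads
   and the within-order null correctly finds nothing.
3. Nests sit near the pair's home midpoint (jittered, minimum spacing
   enforced; impossible packings raise an explicit error), which produces
   the planted spatial carry-over: high-affinity dyads nest closer.
4. Feeder events: per feeder-day, a Poisson number of events (default 15)
   at starts separated by ≥ 15 min; membership is sampled sequentially — a
   seed bird by distance kernel, further members with weight kernel × (1 +
   `affinity_strength` × mean affinity to the birds already in the flock);
   flock size 1 + Poisson(3).  Birds emit nothing before their arrival day
   (uniform over the first 60 days).
5. Box visits: solo visits near home, joint pair visits (within 60 s) at
   the future nest box, and affinity-weighted non-pair joint visits so the
   co-inspection covariate varies off the diagonal.
6. EPP flags are drawn from a logistic model applied to the **realized**
   covariates: the generator runs the package's own event/network/
   geometry/co-inspection machinery (gap detector), 2-SD-scales the
   eligible-dyad covariates exactly as the analysis will, and draws
   Bernoulli outcomes from `epp_betas`.  Fitted coefficients therefore
   estimate the generating values directly, up to sampling noise.

Default `epp_betas` (2-SD scale): order −2.48, male age +0.7, strength
+1.0, arrival difference 0, co-inspection +0.4, intercept −1.5.  The
slopes mirror the effect-size pattern reported for this study system
(strong distance decay, adult-male and association advantages, no arrival
effect); the intercept is a desk-scale choice that realizes a ~5–10%
dyadic EPP rate in a 90–120-bird colony — the field-scale intercept would
leave almost no events at these sizes.  Defaults otherwise emulate the
field design: 20 feeders, a 1 Nov – 14 Mar season, ~15 events per
feeder-day with mean flock size 4, staggered arrival.  Deliberately *not*
emulated: heterospecific flock members, within-flock dominance, antenna
error (missed/ghost reads), breeders absent in winter, and genetic
parentage (EPP outcomes are ground truth, not inferred from genotypes).
Passing tests therefore show the chain recovers structure of this kind
from clean detection data; they do not certify robustness to detection
error or to generative mechanisms outside this family.

`simulate_dyad_table` is a companion dyad-level generator (no detection
layer) emulating the eligible-dyad table of a ~120-bird colony; it exists
for inference-stage calibration studies, where the detection layer is
irrelevant under the null.

## Validation studies (run by the test suite)

* **Type-I error**: 500 dyad-table replicates with no planted strength
  effect, within-order permutation with n_perm = 200 — rejection rate at
  α = 0.05 must fall in 5% ± 2% (measured: 4.8%).
* **Recovery**: 20 full-chain colonies (90 birds, 12 feeders, 50 boxes,
  92-day season, 8 events per feeder-day, n_perm = 200).  The sizes are
  the package's replicate-study design point: large enough for ~80–130 EPP
  dyads per colony, small enough to replicate.  A pre-registered run of
  this exact study fixed the frozen thresholds: mean recovered EPP
  strength coefficient within ±0.2 (3 MC standard errors) of the planted
  1.0, planted effects flagged significant in ≥ 80% of replicates, signs
  recovered, and |mean arrival coefficient| ≤ 0.2 for the absent effect.
* **Gradients**: over the same 20 colonies, mean winter association
  strength decreases strictly across neighbourhood orders 1→5, and the
  category ordering social pair ≥ EPP partner ≥ direct neighbour ≥
  second-order neighbour holds in expectation.
* **Oracle equivalences**: mixture vs gap event partitions on 100 random
  separated-burst layouts; neighbourhood order vs breadth-first search;
  Voronoi cells and adjacency vs an independent half-plane construction;
  IRLS vs the closed-form 2×2 odds ratio (and statsmodels GLM); category
  test vs exhaustive label enumeration.

## Known limitations

* Presence is one contiguous window; birds that truly left and returned
  inflate their denominator (y terms), deflating SRI.
* The gap and mixture detectors agree only on separated gatherings; SRI
  from heavily overlapping gatherings is detector-dependent.
* Outside-range significance flags for non-permuted covariates are
  reported but meaningless (see above).
* The boundary polygon must be supplied (or is the synthetic site
  rectangle); territory shapes near a poorly chosen boundary are
  arbitrary.
* Monthly windows assume the season spans Nov–mid-Mar; other seasons get
  a generic 3/5 early–late split.
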