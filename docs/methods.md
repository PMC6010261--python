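# Methods

This note documents the models, rules, parameters and numerical choices
behind `riverscape`, what the synthetic riverscape generator does and does
not emulate, and the known limitations.

## Network model and accumulation

A riverscape is a forest of in-trees: every reach points to at most one
downstream reach, and terminal reaches drain to an `ocean`, `great_lake`
or `interior` sink.  Braided or artificial channels cannot be represented;
reaches failing single-downstream validation are flagged isolated and
excluded from all downstream totals rather than repaired or imputed.
Likewise, a reach missing a covariate needed by a layer is marked
unclassifiable for that layer only — partial classifications are
first-class, and typology assembly excludes reaches unclassifiable in any
active layer.

All upstream metrics are computed in a single pass over a topological
order (iterative Kahn ordering, no recursion), so million-reach chains are
handled and every metric is O(n) for the whole network:

- **sum-inclusive accumulation** — local value plus all upstream values;
  applied to local catchment areas it yields cumulative drainage area.
- **area-weighted mean** — used for upstream landcover percentages.  When
  local percentages are consistent with their catchment areas this equals
  the percentage of upstream cumulative area under that landcover.
- **DCI** (percent) — upstream network length reachable without entering a
  dammed reach, over total upstream length.  Conventions: the dammed reach
  terminates traversal and its own length is excluded from the functional
  network; the focal reach's own length is excluded from both numerator
  and denominator; a headwater (nothing upstream to fragment) takes
  DCI = 100.  Results are clipped to [0, 100] to absorb float roundoff.
- **DOR** (percent) — upstream impoundment storage over annual runoff
  volume, the latter accumulated from the per-reach runoff-depth covariate
  as depth(mm) · area(km²) · 1000 m³.  Storage on the focal reach counts
  by default (a dam at a reach regulates it); `include_focal_storage=False`
  reverts to strictly-upstream storage.  Zero runoff volume yields NaN
  (undefined), never a division error.
- **terminus connectivity** — a reach is connected iff its downstream path
  crosses no dammed reach (its own dam does not disconnect it) and its
  subnetwork terminates in an ocean or Great Lake; interior sinks are
  disconnected by definition.

## Layer partitions

Threshold layers (size, gradient, temperature, substrate) use left-closed
right-open intervals with open-ended extremes, so the partition is total,
exclusive and monotone; boundary values (e.g. area exactly 10 km²) belong
to the upper class.  Temperatures outside the calibrated 12–30 °C span and
substrate diameters above the top boundary clamp into the end classes
rather than erroring, because model-extrapolated values routinely exceed
the span the partition was derived on.

Confinement is a rule layer on the width ratio r = valley-bottom width /
bankfull width and the coverage c (fraction of reach length with a valley
bottom): unconfined iff r ≥ 4 and c ≥ 0.5; moderately confined iff
(r ≥ 4 and 0.25 ≤ c < 0.5) or (2 ≤ r < 4 and c ≥ 0.5); confined otherwise.
The rule table is exhaustive and exclusive by construction and is
property-tested over a (r, c) grid.

### Temperature partition derivation

`derive_temperature_partitions` re-derives boundaries from data by 1-D
k-means over k = 2…15, choosing k* as the k with the **largest relative
drop** in within-group SSD over k−1 (drops below 10% never count; a flat
profile falls back to k_min).  A literal "largest k with >10% improvement"
rule is not usable: 1-D quantization error scales like 1/k², so relative
improvements decay smoothly (~2/k) and would stay above 10% far past any
real elbow, selecting k_max on entirely unstructured data.  The
largest-drop rule spikes at the true group count on separated data and
selects the minimum k on a single Gaussian, which is the behaviour a
practitioner expects of an elbow criterion.  Derived boundaries are the
midpoints of adjacent sorted cluster centers and are used only when
explicitly configured; the published default boundaries otherwise stand.

### Predictive layers

Hydrology and bankfull width are empirically extrapolated layers served by
sklearn-compatible estimators:

- `HydrologyClassifier` — default random forest (200 trees), reporting a
  cross-validated held-out accuracy at fit time and exposing per-reach
  class-probability vectors (which the uncertainty scenarios consume).
  Training requires ≥ 2 classes with ≥ 5 samples each; the pipeline-level
  `fit_models` drops classes below that support before fitting, mirroring
  how rarely gauged flow-regime classes behave in practice (they remain
  predictable only as their nearest well-sampled neighbour).
- `BankfullWidthModel` — default OLS fit of log w on log A and log P, the
  downstream-hydraulic-geometry power law w = aA^bP^c.  The log-log linear
  default (rather than a tree ensemble) is deliberate: it is the standard
  model family for channel geometry, guarantees strictly positive
  predictions, and recovers a noiseless power law essentially exactly,
  which piecewise-constant tree ensembles cannot.  Any regressor on the
  log design can be substituted via `model=`.

## Typologies, diversity, rarity

Typology codes join the active layers' classes in the fixed order
size-gradient-hydrology-temperature-confinement-substrate.  The diversity
score is C/Ĉ with Ĉ = ∏Kᵢ; the subset scan evaluates the full six-layer
set and all five- and four-layer subsets (22 subsets), and the automatic
selection takes the score-minimizing subset after excluding substrate by
default (its weak contribution to uniqueness and poor predictability make
it the canonical exclusion; any exclusion set can be passed).  Ĉ can
multiply either the published per-layer cardinalities (default) or the
cardinalities realized in the data.

Class summaries rank typologies by total length ascending (rank 1 =
rarest), breaking length ties lexicographically by code so ranks are
deterministic.  Rarity uses the nearest-rank percentile of the
class-length distribution: a class is rare when its total length does not
exceed the ceil(p/100·N)-th smallest class length (default p = 10).  The
percentile is taken over the class-length distribution, not the class
count; with heavy ties every tied class at the cutoff is flagged rare.
Classes with under 1 km of cumulative length are treated as potential
artifacts of coarse predictor data and dropped before prioritization;
ranks and rarity are recomputed on the survivors.

## Disturbance cascade and associations

The ordered cascade assigns the dominant disturbance class as the first
matching condition in: impoundment; DOR ≥ 4%; DCI < 75%; cumulative
disturbance index (NFHP-style ordinal) at moderate/high/very high.  A
reach matching none is not disturbed.  The cascade is evaluated per reach
and is invariant to the evaluation order of non-matching conditions
(property-tested over all 2⁴ combinations).

Layer–disturbance association uses the r×c contingency table of reach
counts (not length-weighted; a weights option is out of scope), Pearson χ²
without continuity correction plus the likelihood-ratio G statistic, and
the strength measures φ = √(χ²/n), contingency coefficient √(χ²/(χ²+n)),
and Cramér's V = √(χ²/(n·min(r−1, c−1))).

## Uncertainty scenarios

Each threshold layer carries a per-reach value deviation; a scenario
re-classifies a reach to the adjacent class across the nearest partition
boundary crossed by value ± deviation (strictly inside the band;
equidistant crossings resolve to the lower class; zero deviation is the
identity).  Hydrology varies to the second-highest-probability class
whenever it is varied at all.  Confinement varies by probing the four
corners of a (ratio ± Δr, coverage ± Δc) band and taking the nearest
corner that lands in a different rule class.  Variant classes are always
adjacent to the originals for threshold layers.  Scenario tables are
rebuilt with each scenario's own rarity computation, and agreement with
the original typologies is the length-weighted percentage of reaches with
identical codes (and identical rare/not-rare status).  Default bands are
zero — deviations are data/model properties the caller supplies (e.g. a
predictor's residual sd) — so the identity scenario is exact by default.

## Prioritization

D(X_r) = L + d/(1 + exp(s·(X_r − X₀))) with defaults L = 0.4, d = 0.5,
s = −0.0125.  "Frequencies surpassing D" is a strict inequality.  X₀
defaults to the cumulative-length inflection: the largest rank such that
the classes more abundant than it jointly hold ≥ 90% of total stream
length (quantile configurable; an explicit X₀ overrides).  Selections:

- conservation — rare class ∧ reach not disturbed;
- restoration — class frequency > D ∧ reach disturbed ∧ reach sampled
  since the cutoff year (default 1990);
- monitoring — class frequency > D ∧ entire class unsampled since the
  cutoff.

Conservation∩restoration and restoration∩monitoring are empty by
construction; conservation and monitoring may share classes, so the union
row of the summary counts each reach once.  Rare classes are not
additionally required to exceed D for conservation.

## Synthetic riverscape generator

Topology grows by random upstream attachment from one or more outlet
reaches (default 3 subnetworks): with probability `branching_prob` a new
reach attaches to a reach that already has one upstream neighbour
(creating a confluence, capped at two), otherwise to a current tip.  This
always yields a valid forest whose order-frequency distribution decays
like a dendritic network's.

Attribute couplings and their defaults (chosen as round, field-plausible
magnitudes for a temperate, low-relief riverscape):

- reach length lognormal (median 1 km, σ = 0.5); local catchment area
  lognormal (median 2 km², σ = 0.7);
- slope = 0.02 · A_cum^−0.45 · lognormal noise (σ = 0.6) — the classic
  slope–area decay;
- summer temperature = 16 °C + 1.3·log₁₀(A_cum+1) − 4.0·elevation(km)
  + a per-subnetwork latitude offset (±2 °C) + N(0, 0.8) — warming
  downstream, cooling upslope, regional coherence;
- hydrology: one latent flow-regime class per subnetwork outlet, inherited
  upstream with switching probability 0.1; class-conditional covariates
  place adjacent class means 2σ apart on each of 5 informative covariates
  (alternating sign per covariate), so misclassification concentrates
  among generatively adjacent classes;
- valley geometry: valley width and coverage decline with the slope
  percentile (confinement–slope coupling), widths scaled by A_cum^0.2;
- bankfull width = 1.2 · A^0.42 · P^0.5 · lognormal(σ = 0.1);
- substrate: Dirichlet compositions whose expectation shifts from
  fines/sand toward boulder/bedrock with the slope percentile;
- dams: placement probability ∝ √A_cum scaled to a network-average rate
  (default 0.08); storage lognormal (median 5·10⁵ m³, σ = 1.5); a dam
  impounds its own reach plus upstream reaches within 2 km of path length
  (a backwater stand-in for waterbody polygons);
- landcover: % urban and % agriculture drawn at outlets (exponential,
  means 8 and 25) and inherited upstream with AR mixing (ρ = 0.8), clipped
  to [0, 100]; the cumulative disturbance ordinal is a quantile cut of
  urban + 0.5·agric, hence monotone in landcover pressure;
- biological samples: a uniform 15% of reaches, taxa uniform over fish /
  mussel / crayfish, years uniform 1970–2017.

Everything is deterministic given the seed (attribute and disturbance
stages derive independent substreams from it), and every emitted table
passes core validation.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: geometric sinuosity and real drainage
geometry; discharge dynamics beyond monotone couplings; spatially
continuous climate fields (regionality is a per-subnetwork scalar);
observation bias in gage/survey placement; historical disturbances absent
from present-day landcover.  Recovery results (hydrology accuracy,
bankfull R²) certify the estimators under the stated couplings and noise,
not performance on any real basin.

## Problem sizes used in the test suite

The suite exercises networks of 60–800 reaches; oracle-equivalence checks
run 1,000 random trees of 5–200 reaches against exhaustive-traversal
oracles; recovery checks use n = 500 reaches (10 seeds) for hydrology and
n = 1,000 training sites (5 seeds) for bankfull width.  These sizes give
stable statistics for every property tested while keeping the whole suite
fast enough to run on every change.

## Known limitations

- Bidirectional (diadromous) connectivity variants and barrier-passability
  weights are out of scope; DCI here is upstream-only.
- χ² associations are reach-count based; very unequal reach lengths can
  make count-based and length-based associations diverge.
- The NFHP-style cumulative index is consumed as an ordinal input; its
  construction is not modelled.
- GLM-based effect-size modelling of continuous disturbance variables is
  deliberately left to standard statistical tooling; only the categorical
  association statistics are part of the package contract.
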