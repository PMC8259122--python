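# Methods

## Scope and data model

The toolkit measures *potential* spatial accessibility of a population to
hospital care and validates it against *revealed* accessibility. Demand is
represented by areal-unit centroids (id, coordinates, population, optional
zone); supply by hospital points (id, coordinates, capacity, care tier
High/Low, urbanization class Metro/City/Rural, specialist count); travel by
a dense demand × hospital matrix of minutes. Travel times are synthesised
as straight-line distance at a constant speed (planar km coordinates by
default, haversine on lon/lat supported); a matrix of observed network
times can be imported instead, and all downstream code only sees minutes.

A pair (i, j) is *in catchment* when τ_ij ≤ threshold, with the boundary
closed (τ = threshold counts as reachable) and 60 minutes as the default
threshold. Catchments are kept as an explicit bipartite structure so the
hospital-side and demand-side views stay consistent by construction.

## Hospital choice model

Hospital choice follows a conditional logit: utilities are linear in tier,
urbanization (Metro reference), specialist count and travel time, and the
choice probability is the softmax of utilities over the option set.
Everyone at one demand point shares one probability row — the population
of a centroid is treated as homogeneous in preference. The softmax is
computed with max-subtraction so coefficient magnitude can never overflow.

Two option-set conventions are provided because the supply-ratio and
accessibility formulas index different sets:

* **catchment** (default): probabilities renormalized within J_i. The
  accessibility sum then telescopes and total population-weighted access
  equals total allocated supply exactly — the property the conservation
  tests assert.
* **global**: probabilities over every hospital. In-catchment probability
  mass can then be < 1; this is the right form when comparing against
  revealed utilization, because the in-catchment mass of a zone is exactly
  the model's expected timely-visit share (its expected TRI). Conservation
  does not hold under this convention.

Coefficient estimation is a Newton maximisation of the conditional-logit
log-likelihood with analytic gradient and observed information, zero start,
step-halving on any likelihood decrease, convergence at gradient norm
< 1e−6 and a 200-iteration cap (a diagnostic error beyond it). Standard
errors come from the inverse observed information. Data that separate
(a covariate predicting the choice perfectly) yield divergent estimates;
the fit detects implausible magnitudes or exploded standard errors, warns,
and flags the result unstable rather than failing. A covariate constant
within every option set makes the model unidentifiable and is rejected up
front. The implementation is cross-checked in the test suite against an
independent grouped conditional-logistic fit and, for two-alternative data,
against a binary logit on covariate differences.

## Accessibility metrics

All four metrics share the ratio-then-sum FCA skeleton and differ in how
demand is apportioned:

* **clmFCA** — by choice probabilities: R_j = S_j / Σ_i D_i P_ij,
  A_i = Σ_{j∈J_i} R_j P_ij.
* **2SFCA** — full population counted at every reachable hospital.
* **3SFCA** — by a travel-time selection weight G_ij = W_ij / Σ_k W_ik.
* **M2SFCA** — decay applied to both sides, A_i = Σ_j S_j W_ij² / Σ_k D_k W_kj,
  so measured access is deliberately below total supply when travel costs
  anything.

The supply-to-demand ratio is a per-hospital quantity (its defining
formula has no demand-point dependence on the right-hand side). Hospitals
whose apportioned demand is exactly zero have an undefined ratio; they are
reported as stranded supply and contribute nothing, rather than being
treated as infinitely accessible. Scores are raw supply-per-person;
a ×10⁴ display scaling is offered as formatting only.

The decay weight W is Gaussian, exp(−τ²/b) with b chosen so that
W(threshold) equals a floor weight (default 0.01), zero beyond the
threshold; a binary family (1 inside, 0 outside) is also provided. The
floor anchoring makes the decay parameterisation threshold-relative, so
changing the threshold rescales the curve rather than re-tuning it.

## Revealed accessibility and comparison

The timely relevance index of a zone is the share of its observed visits
that reach a hospital within the threshold. Zones without visits are
missing, not zero. Potential scores are aggregated demand-point → zone by
population-weighted mean (plain mean if a zone's recorded population is
zero), and compared to TRI by Spearman (average ranks on ties) and Kendall
tau-b (tie-corrected — scores tie frequently in practice); zones lacking
either value are dropped pairwise, and fewer than three overlapping zones
is an error rather than a degenerate coefficient. Benchmark-minus-clmFCA
differences and the count of zones where a benchmark scores higher are
reported alongside.

## Synthetic landscape generator

The generator emulates the structure of a national obstetric-care system
at desk scale. Defaults (all overridable in `LandscapeConfig`):

* **Region and demand**: a 300 km square; 400 centroids, 70% drawn from 5
  Gaussian urban clusters (sd 10 km), the rest uniform; populations
  log-normal (log-mean 7.8 rural / 8.6 urban, log-sd 1.1), giving a heavy
  right tail and an urban-concentrated population.
* **Supply placement**: 60 hospitals anchored to demand points sampled with
  weight ∝ population^1.5 plus 3 km jitter. The super-linear exponent makes
  supply concentrate faster than population — low-demand areas lose
  providers, producing the under-served periphery that motivates
  accessibility analysis in the first place.
* **Attributes**: urbanization labels from terciles of population mass
  within 15 km; high-tier probability (0.30/0.15/0.05) and Poisson
  specialist means (6/3/1) by class, so attractive, specialist-rich
  hospitals sit disproportionately in metros.
* **Capacity**: each hospital's bed count is its expected patient volume
  under the choice model times a system-wide rate (8 beds per 1000
  expected patients) times a lognormal occupancy disturbance (log-sd 0.3).
  Hospitals are thus sized to their markets, as they are in any system
  where capacity follows demand; an early design that drew capacities
  independently of demand produced remote hospitals with an order of
  magnitude more supply per expected patient than metro ones — the
  opposite of real hospital markets — and was replaced for that reason.
* **Zones**: each demand point is assigned a municipal-like 25 km grid
  zone for TRI comparison (`zone_cell_km=None` keeps one zone per
  centroid). Revealed-accessibility comparisons are made at this coarser
  level, mirroring how utilization data are published; at single-centroid
  resolution the rank comparison is dominated by hospital-local ratio
  noise and is not informative about any metric.
* **Utilization**: each centroid emits Poisson(population × rate) visits
  (default rate 0.3 per person — visits, including antenatal care, not
  deliveries), split multinomially by its probability row. Simulations
  meant for TRI use the global option set so that revealed travel can
  exceed the threshold, as real travel does. Bypass behaviour is emergent:
  a distant specialist-rich hospital draws visits past nearer ones purely
  through the utility's +0.151 per specialist.

All randomness descends from one seed through spawned generator streams
(layout / populations / sites / attributes), so a config is exactly
reproducible and stages can be varied independently.

### What the generator does not emulate

Road networks (travel time is straight-line at constant speed), transport
modes, temporal variation, within-zone heterogeneity of preferences, and
any calibration to a specific country's registries beyond
order-of-magnitude realism. Because simulated utilization is drawn from
the same choice model the clmFCA uses, the validation pipeline
demonstrates internal consistency and the *mechanism* of the metric's
advantage — it sees preference-driven leakage that distance-decay weights
cannot — not evidence about any particular real system, where the
estimated choice model is itself an approximation.

## Numerical and testing choices

Problem sizes were chosen so the full suite runs in seconds on one core:
conservation is checked on fifty 40 × 8 landscapes (tolerance 1e−6
relative, with sub-conservation for M2SFCA), vectorized metrics against
naive triple-loop references on 10 × 5 instances at 1e−12, probability
normalization at 1e−9, coefficient recovery on 20 000 simulated choices
over a 50-hospital landscape (each estimate within 3 standard errors of
its generating value), simulator-versus-expected-demand consistency at
1e5 visits (< 5% relative error per hospital), and the TRI
rank-correlation comparison over 20 seeded country-scale landscapes
(clmFCA first in a majority). Floating-point output is written at 10
significant digits so file round-trips are lossless at test tolerance.

## Known limitations

* The choice model carries only the five published utility terms; no
  alternative-specific constants, interactions, nesting or random
  coefficients.
* Conservation holds only under the catchment option-set convention;
  analyses mixing conventions must not assume it.
* The exact decay forms used by published benchmark applications vary;
  the Gaussian-with-floor form here is a common literature choice, so
  absolute benchmark scores are comparable only within this toolkit.
* TRI is a proximity-based revealed measure: it validates the spatial
  pattern of accessibility, not its absolute level.
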