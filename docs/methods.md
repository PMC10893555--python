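# Methods

This note documents the models, conventions and numerical choices behind
`signalniche`, what the synthetic-data generator does and does not emulate,
and the known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal space

Per-song traits (duration s, note count, peak/min/max frequency Hz,
bandwidth Hz) are averaged per male, then each trait column is z-scored
with the sample SD (ddof = 1) and the 6×6 correlation matrix is
eigendecomposed. Components with eigenvalue strictly greater than 1 are
retained (Kaiser rule), in descending-eigenvalue order with ties broken by
trait order. A numerical guard (threshold + 1e-10) keeps an eigenvalue
equal to 1 up to floating-point noise from being retained, so the boundary
case behaves as the strict rule intends.

Because an eigenvector's sign is arbitrary, each component is flipped so
its largest-magnitude loading is positive. All downstream quantities
(areas, intersection areas, centroid distances) are invariant to this
choice; the convention only fixes plot orientation and score signs for
reproducibility.

The PCA stage is exposed as a scikit-learn transformer
(`SignalSpacePCA`), so it composes with sklearn pipelines; fitted
attributes carry trailing underscores (`loadings_`, `eigenvalues_full_`,
`mean_`, `scale_`).

Degenerate inputs: a constant trait column makes the correlation matrix
undefined and raises an error naming the column; fewer than two retained
components triggers a warning at fit time and a hard error only where 2-D
geometry actually starts (`build_niches`), since the PCA itself is still
meaningful.

## Niches and overlap geometry

A niche is the convex hull of a species' male scores (Qhull vertex set;
area via the shoelace formula; area-weighted polygon centroid). Species
with fewer than 3 males or exactly collinear scores raise a named
degenerate-niche error rather than yielding a zero-area polygon — a
zero-area niche would make proportion overlap undefined, and in practice
(minimum 4 males per species) it signals a data problem.

Intersections and unions use exact convex-polygon clipping (shapely),
with two tolerances: coordinates within 1e-9 PCA units are snapped during
clipping, and intersection areas below 1e-12 are reported as exactly 0.
The epsilon matters because the count-based statistics treat *any* nonzero
overlap as an overlap; floating-point slivers at touching boundaries would
otherwise inflate the counts. A corollary of the rule: hulls that touch at
a point or an edge (zero area) do not count as overlapping.

`community_area` defaults to the convex hull over *all* males' scores (the
spanning hull: two disjoint clusters still yield one connected area); the
union of per-species hulls is available as `method="union"` and is never
larger.

The proportion of a focal niche overlapped by a group is
area(focal ∩ union(others)) / area(focal), by clip-then-union — each other
hull is first clipped to the focal hull and the clipped convex pieces are
unioned, so overlapping intruders are never double-counted. Group rows are
produced for every species (migrants included), with groups `migrant`,
`breeding` (excluding the focal species itself) and `total` (all others).

The χ² goodness-of-fit test on realized overlap counts by pair type
defaults to **equal expected proportions** across the three pair types.
The availability-weighted alternative (expected ∝ 209/55/171 possible
pairs out of 435) is exposed via the `expected_proportions` argument and
gives a different statistic; the default is the documented convention, not
a claim that pair availability is irrelevant.

## Phenology and community reconstruction

Checklist filters: keep a checklist iff it is complete, its protocol is
stationary or traveling, its date lies in the season window (April 1 –
June 15), and it has ≤ 10 observers, ≤ 5 h duration and ≤ 5 km distance.
Boundaries are inclusive — exactly 10 observers, exactly 5 h, exactly 5 km
are kept; only strict exceedances are rejected. Duplicates are identified
by checklist id only (shared group checklists with distinct ids are
retained, as no stronger duplicate criterion is defined). The rejection
tally counts violations per rule independently, so a doubly bad checklist
increments two rules but is dropped once.

Day-of-year integers use leap-year numbering (day 96 = April 5, day 158 =
June 6); `to_day_of_year` shifts non-leap dates after February by +1 so
the anchors hold in every year.

Occurrence on day *d* is 100 × (checklists reporting the species on *d*) /
(checklists on *d*). Days with zero checklists yield *missing*, not 0% —
0% would fabricate absence evidence. Daily values are averaged over
consecutive non-overlapping 3-day windows (the 63-day study span gives
exactly 21), with missing days excluded from a window's mean. Presence in
a window requires mean occurrence ≥ threshold (default 1.5%, boundary
inclusive).

Year pooling: by default daily occurrence pools checklists across
replicate seasons for each calendar day before window-averaging;
`per_year=True` computes occurrence per year first and averages across
years. With balanced designs the two agree exactly (a test asserts this);
they diverge only when checklist effort is unbalanced across years.

## Overlap dynamics models

Per window, overlap counts and proportions are recomputed over co-present
species only. Window midpoints are centered to mean 0 and scaled to SD 1
(ddof = 1) before building polynomial terms; polynomials are raw powers of
the standardized day by default (centering already tames the
odd/even-term correlation), with an orthogonal-basis option.

Counts are fitted with a Poisson log-link GLM
(`n_overlaps ~ pair_type * (d + d² + d³)`), proportions with a
**fixed-effects** binomial logit GLM. The classical treatment of such
proportion data uses a species random intercept; that random effect is
deliberately omitted here — mixed-model machinery is a large cost
orthogonal to the geometry this package is about, and this model family is
prone to severe overdispersion anyway — with species available as a fixed
covariate and the omission recorded in the run manifest. Area proportions
are not true counts, so each observation enters with a stated binomial
weight (default 100); the Pearson-residual dispersion statistic is always
reported to flag both the weight's arbitrariness and overdispersion.
Degrees 1–3 are fitted for an AIC comparison whenever the default model is
used. IRLS runs to relative tolerance 1e-10 or 100 iterations; perfect
separation is detected and flagged (`diverged`) rather than silently
reported as huge coefficients.

The paired t-test comparing overlap by migrants vs by breeders runs at the
peak-richness window; among tied windows one is chosen with a fixed seed.
Conventions for degenerate differences: all-zero → t = 0, p = 1;
zero-variance nonzero → ±∞ with p → 0.

## Dispersion null model

Axis ranges are the observed per-axis min/max of the male scores. Each
null replicate draws every male's coordinates independently and uniformly
in that box, preserving species count and per-species sample sizes; a
species' null centroid is the **mean of its sampled points** by default.
The observed side always uses the hull centroid from the niche geometry.
A hull-centroid null is available (`centroid="hull"`, requiring ≥ 3 males
per species). The two null conventions give concordant classifications,
but not identical Z: hull centroids of uniform samples concentrate tighter
than point means, so the hull-null Z runs systematically higher (roughly
10–20% on well-sampled communities). The convention in effect is recorded
in the output.

Null SD uses the sample convention (ddof = 1) by default; population SD is
a flag. At 10⁴ replicates the difference is negligible, but the flag pins
the convention for exact small-sample checks. Alongside the normal-theory
Z classification (two-sided α = 0.05, ±1.96), an empirical two-sided p
with the +1/(n+1) correction is always reported, so inference need not
lean on normality of the null.

Per-pair tests resample **only the pair** (at its observed sample sizes)
within the full observed ranges, matching the community test's recipe
applied pairwise; resampling the whole community per pair is deliberately
not offered, to avoid two silently different definitions. The point-mean
null accepts species of any size ≥ 1 (the two-singleton case is a useful
analytic check: the null mean equals the mean distance between two uniform
points in the box, ≈ 0.5214 for the unit square).

## Phylogenetic signal

Patristic distances are summed branch lengths between tips (dendropy).
Log centroid distance is regressed on patristic distance with a pair-type
interaction; per-type simple slopes come from linear combinations of the
coefficients with delta-method SEs. Tukey HSD contrasts compare adjusted
type means at the mean patristic distance (configurable), using the
studentized-range distribution with k = number of types and the residual
df. Pairs with exactly coincident centroids are excluded from the log-scale
fit with a warning (no offset is added). Pairwise distances are not
independent observations; the fit reports n_pairs and makes no correction,
mirroring the pairwise design it implements.

## Synthetic data generator

The generator emulates: (i) per-species six-trait song means with a
two-factor structure — a spectral factor moving min/peak/max frequency as
a block and a temporal factor driving duration, note count and bandwidth —
plus between-individual and within-individual Gaussian variance
components; (ii) checklist occurrence with species-specific
arrival/departure phenology (symmetric triangular detectability curve by
default — two parameters already in the profile; Gaussian and constant
curves as options), detectability scaling, and a configurable fraction of
planted quality-filter violations; (iii) ultrametric Yule phylogenies with
optional Brownian trait evolution (variance ∝ path length) to induce
positive phylogenetic signal.

Default study conditions (`default_community`): 19 migrant and 11 breeding
species; breeders arrive days 100–118 and stay past the study window,
migrants pass through on staggered 9–16-day stopovers between days 116 and
158; per-species sampling depth ~15 ± 4 males (breeders) and ~8 ± 5
(migrants), clipped to 4–24, with ~8 songs per male; between-individual
trait SD 8% of the species mean and within-individual SD 4% (variance
components are not published for this system, so these are stated
conventions, not estimates — override them in the profile when fitting a
real community). Trait draws sit in wood-warbler ranges (durations
0.5–4 s, 2–30 notes, frequencies ~2.5–9.7 kHz).

What the generator does **not** emulate: no audio or spectrograms, no
spatial/site structure, no observer heterogeneity beyond the planted
filter violations, no multi-year trend (replicate seasons are exchangeable
"years"), and species are statistically independent given their profiles —
there is no built-in character displacement or attraction. Passing tests
therefore demonstrate correctness of the computations and calibration of
the tests under these idealised conditions, not ecological conclusions
about any real community.

Every generator function takes an explicit integer seed and uses a single
private random stream; identical seeds and profiles give byte-identical
tables.

## Problem sizes used by the test and acceptance runs

The packaged runs use sizes chosen to exercise every code path at
comfortable statistical resolution: the demo community is the full
30-species configuration (~330 males, ~3,200 songs, 30 checklists/day over
days 92–167); geometry is cross-checked against 10⁵-sample Monte Carlo on
55 random configurations; null-model calibration uses a 10-species ×
5-male community with 500 repeats of 2,000 replicates; GLM/OLS coverage
uses 100 seeded replicates per model family; the community dispersion test
in the acceptance script uses 10⁴ replicates and the per-pair sweep 2,000
per pair.

## Known limitations

- Convex hulls are sensitive to extreme individuals; niche area grows with
  sampling depth (the sample-size regression quantifies this but no
  correction is applied, by design — the diagnostic VIF output shows why a
  status-by-depth correction is not identifiable in unbalanced designs).
- The binomial time-course model treats hull-area proportions as weighted
  binomial data; its likelihood is a working approximation and the
  dispersion statistic should always be read alongside the coefficients.
- The uniform-box null ignores the observed correlation between PC axes
  and any non-uniform density of signal space; Z scores answer "more
  dispersed than uniform random placement", nothing stronger.
- Pairwise records (overlap, dispersion, phylogenetic regression) are
  non-independent; reported p-values are conditional on the pairwise
  design.
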