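# Methods

This note documents the statistical procedures, the synthetic
data-generating process, the numerical conventions, and the design choices
made where more than one defensible option existed.

## Weak supervision and the split convention

Positive labels are structural, not annotated: every post title in the
seed themed community and its link neighborhood is positive. Neighborhood
expansion takes the union of in- and out-link neighbors of the seed,
keeps those with at least `min_posts` (default 1000) posts, and always
retains the seed itself. Negatives are an equal-count uniform sample
*without replacement* from all other communities; if the pool is smaller
than the positive set the build fails loudly rather than oversampling.

Splitting is a seeded shuffle followed by floor allocation:
`|train| = ⌊f_tr·n⌋`, `|val| = ⌊f_val·n⌋`, remainder to test. At the
reference corpus size of 651,271 this gives 521,016 / 65,127 / 65,128. The
three published partition counts for this regime sum to one less than the
corpus, so some convention for the leftover example was unstated;
remainder-to-test preserves the printed train and validation counts and is
frozen here as the package's convention. Inputs are sorted on a canonical
key before the seeded shuffle so a permuted input file yields an identical
split.

## Classifier

The default model is a token-count logistic regression (L2, strength 1.0,
i.e. scikit-learn `C = 1`), trained with lbfgs to tolerance 1e-8. The
tokenizer lowercases and splits on characters outside `[a-z0-9#']`,
keeping `#`-initiated tokens intact so hashtags act as ordinary features.
The regularization strength is a package default, not an empirically tuned
value; downstream stages consume only the probability-and-threshold
contract (call positive iff p ≥ 0.5, boundary inclusive), so any external
model exposing `predict_proba` in [0, 1] is interchangeable. Out-of-range
adapter outputs raise at the call site rather than propagating.

## Enrichment screen

Per hashtag, presence is per-tweet (set semantics — a hashtag repeated
inside one tweet counts once), crossed with the classifier call into a 2×2
table. The test is the Pearson χ² without continuity correction; with one
degree of freedom the statistic equals the squared two-proportion z, so
the one-tailed *greater* p is exactly `p_two/2` when the hashtag rate
among positive calls exceeds the rate among negative calls and
`1 − p_two/2` otherwise (a zero statistic gives 0.5). Continuity
correction is off by default (configurable); the ≥ 5-occurrence filter
bounds small-sample distortion and is applied *before* correction, so
filtered hashtags never count toward the number of tests m. BH step-up
uses `k = max{i : p(i) ≤ i·q/m}` with ties sharing one all-or-none
decision; the threshold is evaluated exactly as written, `(i·q)/m`, which
keeps boundary cases bit-identical to the definition. Tables with a zero
marginal (e.g. a constant classifier) are degenerate and excluded from
testing rather than assigned a p-value.

## Geography and prevalence

Containment is boundary-inclusive; a point claimed by overlapping areas is
assigned to the lexicographically smallest `area_id`. Both rules are
conventions chosen because real administrative polygons share borders and
no authoritative rule exists; they are deterministic and documented rather
than silent. Unassigned geotags are counted and reported, never dropped —
conservation (`assigned + unassigned = geotagged`) is asserted in tests
and in the pipeline manifest. Prevalence is
`count / mean population × 10,000` with the mean over the configured year
range (default 2013–2018); the scale constant is configurable. Area
inclusion uses ≥ 1 tweet and mean population strictly greater than 1000.
Zero-population areas have undefined prevalence and are flagged and
excluded. No per-user deduplication is performed; repeated tweets by one
user inflate their area's count, a known limitation of the design.

## Association

Crude: Spearman ρ with average ranks for ties and the two-sided
t-approximation on n − 2 degrees of freedom (adequate for the intended
n of roughly 50–2600 areas; no exact permutation p). Adjusted: unweighted
OLS of the outcome on prevalence, the seven confounders, and an intercept,
reporting the prevalence coefficient with its two-sided t-test p.
Confounders are used on their native scale — the coefficient and p-value
on prevalence are invariant to affine confounder rescaling, which is
property-tested. Rank-deficient designs raise a collinearity error naming
the dependent columns; a condition number above 1e8 sets a diagnostic
flag. Missing outcomes are dropped per outcome (pairwise-complete), so n
varies by row. No multiple-testing correction is applied across outcome
rows; each row is reported with its own n and p.

## Synthetic world

The generator emulates the minimal structure the pipeline needs to be
falsifiable, not realistic language:

- **Posts**: bag-of-tokens titles of length 1 + Poisson(8); themed
  communities draw each token from a 50-token theme lexicon with
  probability 0.3, background communities leak theme tokens at 0.02, else
  a 500-token background lexicon (uniform within lexicon). With these
  rates roughly a fifth of themed posts carry ≤ 1 theme token, putting the
  Bayes-achievable held-out accuracy near 0.9 — a deliberately imperfect
  classifier, so discovery is tested under realistic misclassification.
- **Tweets**: a latent indicator z ~ Bernoulli(0.1) selects the token
  mixture; each of 1 + Poisson(0.5) hashtags is planted with probability
  q1 = 0.6 (z = 1) or q0 = 0.02 (z = 0), else uniform over 185 null tags.
  Setting q1 = q0 yields an exact null world for calibration.
- **Geography**: areas are unit grid cells (realistic polygon handling is
  exercised through the GeoJSON reader instead); populations are
  log-normal (median 10⁴, σ = 0.5), drawn once and jittered ±5% per year
  so the mean-population computation is nontrivial; tweets are assigned
  to areas proportionally to population with geotags uniform in the cell.
  The geotag rate is a parameter; the default world is fully geotagged so
  the planted association is exact, while real feeds geotag only a few
  percent of posts — tests on this world say nothing about geotag
  selection bias.
- **Outcome**: `y_a = 10 + true_beta · latent_per10k_a + γᵀx_a + ε`,
  ε ~ N(0, 0.5), with `latent_per10k` the area's geotagged z = 1 tweets
  per 10,000 persons — the same scale the pipeline measures — plus an
  `independent_outcome` generated without the latent term for type-I
  checks. `true_beta = 2`, γ = (0.5, −0.3, 0.2, 0.4, −0.2, 0.3, 0.1).

Determinism: one RNG stream per sub-generator (posts, tweets, geography),
each seeded by SHA-256 of (seed, stream name), so the same seed is
byte-reproducible across platforms and enlarging one component never
perturbs another.

What passing on this world does **not** show: robustness to real language
(slang drift, sarcasm, multilingual text), user-level correlation
structure, network effects, geotag selection bias, or spatial
autocorrelation of outcomes — none of which the generator models.

## Replicated experiments and problem sizes

`taglift.evaluation` runs three experiment families, each regenerating
independent worlds from derived seeds:

- **Planted recovery** (20 seeds, default worlds): sensitivity and
  empirical FDR of the discovered hashtag set against the planted truth.
- **Null calibration** (100 seeds, q1 = q0 = 0.02): selected fraction of
  tested hashtags, which BH should hold near or below the FDR level.
- **Effect recovery** (200 replicates): the adjusted OLS is fit with the
  generator's *true* latent per-10k prevalence as regressor, so the check
  isolates the estimator — unbiasedness of β̂ and nominal 95% CI coverage
  under the generated design. Regressing instead on hashtag-measured
  prevalence estimates an attenuated coefficient (errors-in-variables from
  classification and hashtag noise), visible in the worked example. These
  replicates use 50 posts per community, since community posts do not
  enter the recovered quantity.

## Known limitations

- The default classifier is linear over token counts; it stands on its own
  contract, and the adapter seam exists precisely so a stronger model can
  replace it without touching downstream stages.
- Ecological design: all associations are between area-level aggregates
  and support no individual-level or causal reading.
- Beverage-category stratification relies on the packaged reference
  hashtag categorization; category membership is itself a modeling choice
  carried as data, not inferred.
- Plain lon/lat geometry only; no projection handling or spatial indexing
  beyond an STRtree, which is adequate for thousands of areas but untested
  at continental point volumes.
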