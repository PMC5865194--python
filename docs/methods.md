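# Methods

## Data model and design constants

A survey is four tables (units, presences, arrivals, interactions). The
canonical design, hard-coded as constants and checked by
`antcomp.io.validate_design`, is: 2 habitats (primary / selectively-logged
forest) × 10 sites × 3 grids; per grid one pooled leaf-litter unit (Winkler
bag) and three 40-minute camera bait-card sessions, i.e. 30 litter + 90
camera = 120 analysed sampling units per habitat. Grids map to fixed time
slots (0800/1200/1600). Human-observed bait cards are representable via the
`human` method tag but excluded from every analysis — observer presence
disturbs visitation, so such cards exist only as reference collections.
Design deviations are *warnings*, never errors: partial surveys are
legitimate inputs.

Absence is encoded by absence of a record; presence rows carry abundance
≥ 1 (litter units record presence only, stored as abundance 1). Role pairs
at ingestion may be neutral/neutral, aggressive/submissive (either order) or
aggressive/aggressive: mutual aggression is accepted losslessly even though
a clean dominance encounter has one winner, because real footage contains
it. Classification policy lives downstream: any aggression ⇒ competitive;
mutual aggression scores (2, 2) and is excluded from directed network edges
(counted separately on the graph).

## Aggression scoring and matrices

Scores are 0 (submissive) / 1 (neutral) / 2 (aggressive) per participant.
The pairwise matrix for one habitat means genus *i*'s scores over all its
events against *j*; `n[i,j] = n[j,i]` is the pair's event count. Only genera
with **more than three distinct interaction partners** (`min_partners = 4`)
are retained — partner counts are computed *before* filtering, and matrix
cells then cover retained×retained pairs. On data without mutual aggression
the matrix is complementary: `mean[i,j] + mean[j,i] = 2`.

Score change Δ[i,j] = mean_logged − mean_primary is defined only where
*each* habitat has ≥ `min_pair_n = 3` events for the pair (the stricter
reading of "missing below three pairwise interactions"; applying the
threshold to the pooled count is not offered because it would mix habitats
with very different coverage). The per-genus weighted mean change uses
weights `n_primary + n_logged` by default; `min(n_primary, n_logged)` is
selectable (`weighting="min"`) since the source analysis states only that
weights reflect sample size. Per-card metrics: rate = competitive
interactions / 40 min (reported per minute, with the raw per-session count
alongside); per-capita divides by total ant abundance on the card, with the
numerator defaulting to competitive interactions only (matching the metric's
name) and a flag for all interactions; cards with zero interactions are kept
(rate 0) so habitat means average over all cards, and proportion-competitive
is missing on such cards.

## Networks

Directed edges point aggressor → submissive with weight = event count and a
drawing width of weight/2 pt — the unique linear map through the two anchor
conventions (1 event ↔ 0.5 pt, 16 events ↔ 8 pt); no clamping beyond
16. Antiparallel edges are kept separately by default (lossless); a `net`
view collapses each pair to its dominant direction with the weight
difference, for figure-style rendering where one arrow per pair points at
the overall submissive genus. Exports: edge-list TSV and GraphML
(round-trippable), DOT (write-only).

## Statistics

*Spearman*: fractional ranks; ρ is the product-moment correlation of ranks
(identical to 1 − 6S/(n(n²−1)) without ties); S is always reported as the
raw Σd², with a tie flag when the identity does not apply. p is exact (full
permutation enumeration) for n ≤ 9, t-approximation above. `rho_from_s`
inverts the no-ties identity to recover ρ from a printed S.

*Mann-Whitney U*: delegated to `scipy.stats.mannwhitneyu` — exact null when
the smaller sample has ≤ 8 tie-free observations, tie-corrected normal
approximation otherwise. The test suite cross-checks the exact branch
against an independent brute-force enumeration of all C(n+m, n) group
assignments.

*Between-habitat contrasts* (`forest_contrast`): the site is the independent
replicate (10 per habitat), so p-values use a t reference with
n_sites − 2 degrees of freedom throughout. Families: counts → quasi-Poisson
GLM (Pearson-χ² scale) with cluster-robust SEs by site; binary event
category → binomial GEE with exchangeable within-site correlation;
continuous per-card metrics → the random-site-intercept linear model
evaluated in its exact between-site reduction, a Wald t on per-site means.
The last choice is deliberate: a direct REML mixed-model Wald statistic is
badly miscalibrated here (the site-variance boundary shrinks its tail; we
measured type-I error well below nominal under a null with genuine
site-level variance, while the between-site t is exact for balanced Gaussian
data and measured at 0.042–0.068 over 500-replicate checks). Any estimation
failure falls back to a seeded site-level permutation test (default 10 000
permutations, statistic = difference of habitat means of site means), and
the result is flagged `converged=False` with the fallback's seed recorded.

*Evenness*: OLS of per-unit Shannon H′ (nats, via `scipy.stats.entropy`) on
habitat. Shannon diversity is computed on pooled per-habitat abundance by
default with a per-unit mode exposed; outputs label which was used.

## Synthetic communities

The generator is first-class, tested code: it defines the study conditions
under which the analysis machinery is validated. Per genus *g*, habitat *f*:
litter presence ~ Bernoulli(p_litter), camera-card presence ~
Bernoulli(1 − exp(−λ)), abundance | presence ~ 1 + Poisson(μ), first-arrival
time ~ Uniform(0, 40) with order = rank of times. Each co-present unordered
pair draws Poisson(η) encounters; an encounter is neutral with probability
p_neutral, otherwise *i* aggresses with probability
logistic(β·(d_i − d_j)). This is the minimal standard dominance model —
monotone in d with closed-form limits (p_neutral = 1 forces all-neutral;
β → ∞ makes the higher-d genus win always) that the tests exploit.
Determinism: one `SeedSequence` per dataset, one spawned sub-stream per
sampling unit, so identical params + seed reproduce bit-identical data.

The reference community has 54 Bornean litter-ant genera (19 recorded by
both litter and bait methods, 32 litter-only, 3 bait-only; 22 bait-visiting)
with right-skewed occupancy and arrival rates, ~73.5% neutral encounters,
and lower bait activity in logged forest — the observed scale of such
surveys. Named scenarios (seed-reproducible): **null** (d identical across
habitats), **intuitive** (logged d shifted by 1.5 standardised ranks of the
expected-occupancy change, so dominance change is rank-coupled to occupancy
change by construction), **rewired** (densely sampled design: the 17 most
frequent bait genera at λ = 2 per card, η = 0.5, p_neutral = 0.5, dominance
an evenly spread ladder on [−2, 2] whose logged values are a random
permutation of the primary ones — chosen so frequent pairs accumulate ≥ 30
encounters over 90 cards and hierarchy recovery is a sharp test rather than
a noise measurement). `shuffle_hierarchy(params, k, seed)` re-wires any
params: logged d is reset to primary and k randomly chosen genera get a
non-identity permutation among themselves.

What the generator does *not* emulate: discovery–dominance trade-offs
(arrival order does not influence outcomes), spatial autocorrelation between
neighbouring points, microclimate covariates, abundance-dependent encounter
rates (off by default; an optional mode scales η by the smaller abundance),
and mutual aggression (never generated, only accepted at ingestion). Passing
recovery tests therefore show the scoring machinery inverts *this* outcome
model faithfully — not that real bait-card data satisfy it.

## Numerical choices and degenerate inputs

Rank ties use fractional (average) ranking everywhere, including occupancy
ranks. Overlap percentages are rounded half-up to one decimal.
Rank-occupancy comparisons re-rank within the compared genus subset and drop
(with a warning) genera absent from one habitat. Constant vectors give a
flagged undefined ρ; all-zero abundance vectors are an error for H′; cards
without ants have missing per-capita; empty event sets give an empty matrix
plus warning rather than an error. Score-change requires a non-empty genus
intersection (disjoint sets are an error, not an empty result, since it
indicates mismatched inputs).

## Problem sizes

The test suite and acceptance script run entirely on generated data: the
canonical 240-unit layout, the rewired scenario (~9 000 encounters), fuzzed
micro-instances (≥ 200) for the brute-force oracle comparisons, and a
500-replicate null simulation (10 sites × 9 cards per habitat) for the
type-I calibration of the continuous contrast — sizes chosen to make the
stochastic checks decisive at desk scale.

## Known limitations

Genus-level scoring ignores within-genus variation in behaviour; the 0/1/2
scale is ordinal but the pairwise mean treats it as interval (as the field
convention does); the weighted mean change inherits whatever biases the
partner filter introduces for rare genera; and the GEE/quasi-Poisson
contrasts rely on ≥ 2 sites per habitat and are reported with between-site
df, which is conservative if most information is within-site.
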