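# Methods

## Data model

A dataset is a triple (cases, readers, annotations).  A case carries a
gold-standard *finding set* and a three-level difficulty label; a reader
carries a four-level experience category (senior medical student, recent
graduate, resident outside cardiology, cardiology resident); an annotation
is one reader's coded answer to one case — a finding set, an ordinal
confidence 1–6, and optional self-rated difficulty and intuition flags.

Responses are compared as unordered finding sets: the coding scheme
(presence/absence of each finding) carries no ordering semantics, so two
annotations pool their votes iff their present-finding sets are identical.
"No pathology" is an explicit finding label rather than an empty set;
otherwise a normal reading would be indistinguishable from a missing
answer and could not be voted on.  Validation is total and collects every
violation (confidence range, referential integrity, duplicate
(reader, case) pairs, a minimum of three annotations per case — the
smallest group that can hold a majority vote) into one located error
report; malformed data is never silently repaired.

## Voting protocols

A group's annotations are pooled into a ranked list of distinct responses
under one of three rules: frequency (each member contributes weight 1),
experience (weight = ordinal experience weight) and confidence (weight =
stated confidence).  Experience weights default to the identity embedding
1–4 of the category order.  Only the order of these weights is
identifiable — rankings are invariant to positive rescaling — so the
simplest monotone embedding is used, overridable by any integer-valued
mapping.  Confidence is used as the raw ordinal value with no
recalibration.

Ties are resolved by a uniform random permutation within every tie class,
not only at the top rank: strict accuracy needs only the top choice, but
loose accuracy needs a total order over the first k entries, and permuting
every tie class is the consistent generalization (for k at or beyond the
tie boundary the two coincide).  The random generator used for
tie-breaking is owned by the caller, so bootstrap replicate streams are
reproducible end to end.

## Accuracy metrics

* Group SA = 1 iff the top-ranked finding set equals the gold set exactly.
* Group LA(k) = 1 iff the gold set appears, as an exact set match, among
  the top k ranked responses (default k = 5; the length of a plausible
  "second-opinion menu" is a heuristic, so k is a parameter).
* Individual SA = the reader gave exactly the gold set; individual LA =
  every gold finding is among the reader's findings, extras allowed.

For composite (multi-finding) gold standards, group LA requires the full
composite set within the top k; a containment-based variant (any main
finding present) would be strictly more lenient and is deliberately not
implemented, keeping group LA the exact-match counterpart of group SA.
LA ≥ SA pointwise by construction, and LA(1) ≡ SA.

## Bootstrap estimation

The estimand for one (case, protocol, metric, group size n) cell is the
expected accuracy of a uniformly random n-subset of the case's readers,
with tie-break randomness marginalized.  Readers are sampled without
replacement within a group — a reader sits on a committee once — while
recurring freely across sampled groups.  The procedure:

1. n_cycles = 500 cycles; in each, n_samples = 500 groups are sampled,
   aggregated and scored, and their binary outcomes averaged.
2. The 500 cycle averages are resampled with replacement n_boots = 500
   times; the estimate reports the mean of the bootstrap means, their SD
   and median, and the percentile interval at 95%.  The percentile
   interval is the standard nonparametric default; degenerate populations
   (all cycle averages equal) collapse to a zero-width interval.

Group sizes sweep 3–30.  Cases with fewer readers than a requested size
are truncated to their feasible sizes with a logged warning rather than
aborting the sweep.

### Implementation and randomness

The sweep uses a vectorized kernel.  Within one case and cycle, a single
random permutation of the readers is drawn per sampled group and the
groups of sizes 3..30 are its nested prefixes; every size's marginal
distribution is exactly uniform over size-n subsets, and the correlation
across sizes (common random numbers) only reduces the variance of
size-to-size contrasts.  One sampled group is likewise shared by all
protocols and both metrics, mirroring the procedure's single sampling
step.  Tie-breaking adds U(0,1) jitter to the integer-valued aggregate
weights, which is exactly a uniform random permutation within each tie
class; the jitter draw is shared across protocols, so equal weight tables
yield identical tie resolutions — this is what makes the degeneracy
identity (all confidences equal and all experience weights equal ⇒ the
three protocols produce bit-identical curves) exact rather than
approximate.  The kernel therefore requires integer voting weights; the
per-group `aggregate()` path handles arbitrary positive weights by exact
grouping.  Seeds flow through a `SeedSequence` hierarchy
(seed → case → kernel/bootstrap streams), making the whole sweep a pure
function of (dataset, config, seed); bootstrap resampling plans are shared
across protocols and metrics within a (case, size) so identical cycle
means give identical estimates.

An independent enumeration oracle (`crowdecg.exact`) computes the same
estimand exactly on small fixtures by iterating all C(readers, n) groups
and marginalizing ties analytically: if a distinct responses rank strictly
above the gold response and g are tied with it, P(strictly correct) =
1[a=0]/g and P(loosely correct at k) = clip((k−a)/g, 0, 1).  It shares no
code with the Monte Carlo path and is infeasible at study scale by design.

## Inferential statistics

Group-vs-individual comparisons use a two-sided t-test at α = 0.05: the
group side is the sample of cycle averages, the individual side either the
per-reader binary outcomes (Welch unequal-variance two-sample test — the
conservative reading of "comparing the scores of individuals and groups")
or a scalar baseline (one-sample test).  Zero-variance samples on both
sides return a degenerate, non-significant result with the difference
still reported, instead of a numerical failure.  Differences are reported
in percentage points.  No multiple-testing correction is applied across
cases; results are per-case descriptive comparisons and are labelled as
such.

Correlations are Pearson's ρ (two-tailed p) between per-reader mean
accuracy — each reader averaged over the five cases of their
questionnaire block — and per-reader mean confidence or ordinal experience
weight.  Zero variance on either axis raises an undefined-correlation
error rather than returning NaN.

## Synthetic populations

The generator emulates the data-collection design the analysis assumes:
readers split round-robin into questionnaire blocks of five cases, each
reader independently drawing one coded response per case from the case's
categorical response distribution.

* **Experience mix** defaults to 26% senior students / 51% recent
  graduates / 20% other residents / 3% cardiology residents — the
  composition of a volunteer student-and-young-doctor pool.
* **Confidence** is a discretized shifted Gaussian:
  `clamp(round(N(3.0, 1.0) + s·correct), 1, 6)`.  The base SD of 1.0 is a
  realistic spread for a six-point scale.  The shift s tunes the
  confidence–correctness association; `shift_for_correlation` inverts the
  analytic formula ρ = s·σ_acc / √(s²σ_acc² + σ₀²/5) (σ_acc from the
  binomial accuracy variance over a five-case block), ignoring rounding
  and clamping — the parameter-recovery test bounds that approximation at
  ±0.1 around a target of 0.6.
* **Experience** is decoupled from correctness by default
  (`experience_effect = 0`); a nonzero effect tilts each reader's
  gold-response probability on the log-odds scale by their centered
  experience weight.

Four scenario regimes reproduce the qualitative group-size behaviours of
multi-reader studies.  Gold-response probabilities: plateau 0.70 (clear
modal answer, saturation by size ~10), growth 0.45 with a 0.15 runner-up
(modal but contested: the curve still climbs at size 30 and exceeds 0.95
there), minority_correct 0.10 against a 0.55 dominant wrong answer
(majority voting buries the gold response toward 0), and multi_finding
0.08 for a two-finding composite whose fragments (0.07/0.06) are popular
wrong answers over a long tail of rare responses (slow, near-linear
growth).  Every regime reserves a few percent for a "gold plus an extra
finding" response, which is loosely but not strictly correct — the
over-complete reports that separate individual LA from SA.  The growth
parameters were chosen so that the regime genuinely exhibits
no-plateau-by-30 *and* near-certain accuracy at 30; a narrower margin
(e.g. 0.45 vs 0.25) leaves plurality at size 30 far below that, which is a
property of plurality margins, not of the estimator.

### A note on random vote weights

Weighting votes by confidences that are *uncorrelated* with correctness is
not equivalent to unweighted plurality: a single confident wrong voter can
outweigh two diffident correct ones, so i.i.d. random weights incur a
small systematic accuracy penalty relative to frequency voting.  Exact
enumeration on a 12-reader fixture puts frequency SA at 0.500 and
random-confidence SA at 0.444 for groups of three; at generator defaults
the gap is two to four points.  Confidence weighting only pays off
through the confidence–accuracy correlation — with the correlation
calibrated to 0.6 the confidence protocol beats frequency by ~11–13
points at group sizes ≤ 10 — and the "no correlation ⇒ identical curves"
intuition is only an approximation, exact solely in the degenerate case
of constant confidences.

## Problem sizes

Defaults replicate the 500 × 500 × 500 nested design over group sizes
3–30.  The packaged ten-case study configuration uses 160 readers (two
blocks of ~80, within the per-case reader counts such studies report);
tests and the acceptance script use reduced designs (e.g. 100 × 100
cycles/samples, 100–300 bootstrap resamples) chosen so the whole suite
runs on a single CPU in minutes — estimator properties are
size-independent and the reduced designs keep Monte Carlo error well
inside the asserted tolerances.

## Limitations

The generator draws conditionally independent responses given the case's
response distribution; it does not emulate shared training backgrounds
(correlated errors beyond the marginal response frequencies), free-text
report variability before coding, reader fatigue or case order effects.
Passing tests therefore show that the *estimation and comparison
machinery* is correct and calibrated under the stated population model,
not that real reader pools satisfy that model.  The exact enumeration
oracle is limited to populations where C(readers, n) is enumerable
(~10⁵ groups).  The joint distribution of confidence, experience and
correctness in real studies is unknown; generator parameters are stated
assumptions, not estimates from data.
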