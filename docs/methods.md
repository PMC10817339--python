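# Methods

## The dual-retrieval likelihood

An item's three-test outcome pattern x = (x₁, x₂, x₃) ∈ {C, E}³ has
probability

    P(x) = D · v(x) + (1 − D) · R · ∏ₜ Jₜ^[xₜ=C] (1 − Jₜ)^[xₜ=E]
         + (1 − D)(1 − R) · [x = EEE]

where the verbatim-route term v(x) is (1 − F)² for CCC, (1 − F)F for
CCE, F for CEE and 0 otherwise: direct access recalls with certainty
while the verbatim trace survives, the trace survives each inter-test
interval with probability 1 − F, and a lost trace never returns — in
particular it does **not** re-enter the reconstruction route.  That
assumption and the single forgetting rate shared by both intervals keep
the model at 6 parameters, which is what makes the goodness-of-fit test
a χ²(1): 8 cells − 1 sum constraint − 6 parameters = 1 df.  The
reconstruction route outputs independently on each test with the per-test
familiarity probabilities J₁–J₃, so it contributes to all 8 patterns.

Items are pooled within a condition across participants and treated as
i.i.d. multinomial draws, as in the source analysis tradition;
participant heterogeneity is ignored (see Limitations).

## Estimation and testing

The multinomial log-likelihood ℓ(θ) = Σᵢ Oᵢ ln πᵢ(θ) is maximized over
[10⁻⁶, 1 − 10⁻⁶]⁶ by L-BFGS-B with the analytic gradient, from a fixed
midpoint start plus `n_starts` Latin-hypercube starts (default 20).
Objective tolerance is 1e−12; ties between starts are broken by the
lexicographically smaller parameter vector.  G² = 2(ℓ_sat − ℓ̂) with
0·ln 0 := 0 and probabilities floored at 1e−12 only inside logarithms;
degenerate data (all mass in EEE) return a boundary estimate with a
warning flag rather than an error.  P-values use the χ²(1) survival
function even for boundary estimates.

ΔG² equality tests refit the two conditions jointly with the named
parameter shared (11 free values) and all others condition-specific; the
joint optimizer is additionally warm-started at the two free optima with
the shared parameter set to their count-weighted average.  ΔG² within
−1e−6 of zero (optimizer noise) is floored at 0; larger negatives raise
a diagnostics error, since they can only mean the joint fit missed its
optimum.  The comparison battery mirrors the design's planned contrasts
— item vs none, list vs item, list vs none within each list organization,
for all six parameters — and reports raw p-values (the LSD-style
convention); Holm adjustment is available behind a flag.

**Small-sample caveat.**  The χ²(1) reference for G² and ΔG² presumes
adequate expected counts in all 8 cells.  Our own calibration runs show
nominal behavior (type-I error 0.048, uniform p-values, 2,000 null
replicates at 320 items/condition) when every expected cell count is
≥ ~15, but inflation to ≈ 0.07–0.08 when a parameter regime pushes
several expected counts below ~5 (e.g., small F with modest R at 320
items).  With sparse cells, treat borderline ΔG² rejections with caution
or increase the item count.  The likelihood surface can also develop
local optima on sparse counts — another reason the multi-start default
is 20.

## ARC

ARC is computed exactly as defined: R = adjacent same-category
repetitions in the output order, E(R) = Σnᵢ²/N − 1 (which is the exact
permutation-null expectation), maxR = N − k, minR = 0 if N + 1 ≥ 2m else
2m − N − 1.  The piecewise formula leaves R = E(R) undefined; we define
ARC := 0 there (both numerators vanish, and 0 is the scale's chance
anchor).  ARC is reported as undefined — a value state, excluded from
condition means with exclusion counts logged — when N ≤ 1, only one
category is recalled, or the applicable denominator is 0.  Duplicated
recalls of a word within a test are collapsed to the first occurrence
and intrusions are dropped before ARC.

A property worth knowing: although ARC equals 0 *at* chance-level
repetitions, its **mean** under a uniformly random output order is not 0
— positive and negative deviations are normalized by different
denominators (maxR − E(R) vs E(R) − minR), giving chance means around
−0.1 for typical 5-category compositions.  Chance-level behavior of an
output process is therefore checked on R − E(R), not on mean ARC.

## Synthetic experiment generator

The generator emulates the 2 × 3 between-subjects design: 240
participants allocated to 6 cells (±1), 40 study words = 5 taxonomic
categories × 8 exemplars presented as five 8-word lists, three recall
tests.  Blocked sessions present each category as one contiguous block
(category order and within-block order shuffled per participant);
randomized sessions rejection-sample a global order with no
same-category run longer than 3 (up to 10,000 attempts, though the
expected number of retries for the default composition is close to 1).

Recall outcomes are i.i.d. draws from the dual-retrieval pattern
distribution with condition-specific true parameters.  The default truth
is a realistic reactivity pattern for this design: randomized lists pair
elevated J₁ in the item-JOL cell (.54 vs .34 in the no-JOL cell) with
reduced D and R in the list-JOL cell; blocked lists put the action in F
and J₂ for the list-JOL cell.

Output order within a test follows a category-biased sequential draw:
with probability `clustering_weight` (default 0.5) the next output stays
in the current category while any of its recalled items remain, else it
is uniform over all remaining recalled items.  Weight 1 forces
block-contiguous output (ARC = 1); weight 0 is exactly the uniform
permutation null.  The default weight is shared by all cells, so the
generator's ARC contrast between conditions is null unless configured
otherwise.

JOLs are drawn on their task scales — item JOLs as integer-rounded
normal draws clipped to [0, 100] (default mean 50, SD 25; the underlying
study reports no item-level JOL means, so these are free, deliberately
uninformative defaults), list JOLs as integers clipped to [0, 8] with
organization-specific means 4.89 (blocked) and 3.73 (randomized), SDs
1.19 and 1.06.  JOL values never feed back into recall probabilities:
reactivity is encoded solely through the condition-specific model
parameters, mirroring the design logic that the JOL *task*, not the
rating value, drives reactivity.  Word tokens default to
`<category>_<index>`; a lexicon mapping can replace them.

What the generator does **not** emulate: serial-position effects,
participant-level random effects (every item in a cell shares one
parameter vector), JOL resolution/accuracy, intrusions and misspellings
(transcripts derived from it are clean), and reaction times.  Passing
tests on synthetic data therefore validate the machinery — recovery,
calibration, plumbing — not those aspects of real data.

## Scoring and screening

Typed responses are lowercased, trimmed, whitespace-collapsed, and
deduplicated (first occurrence kept).  A response matches the first
unmatched study word equal to it, else the nearest unmatched word within
edit distance `tolerance` (default 1; ties by study-list order); each
study word matches at most once; the rest are intrusions.  Per-item
flags across the three tests map to the canonical pattern index
4·[t1] + 2·[t2] + [t3].

Outlier screening follows the upper-sided, median-anchored rule: within
each design cell, participants whose mean recall exceeds the cell median
by more than 1.5 IQRs are excluded (quartiles by linear interpolation —
the common default, stated here because conventions differ).  We
implement the rule as printed rather than "correcting" it to symmetric
Tukey fences; a `symmetric` flag provides that variant.  Cells with
fewer than 4 participants skip the filter with a warning.

## Behavioral statistics

One-way fixed-effects ANOVA by sums of squares, with MSE = SS_w/df_w and
η_p² = SS_b/(SS_b + SS_w); LSD pairwise tests use
t = (M_a − M_b)/√(MSE(1/n_a + 1/n_b)) on the ANOVA's df, Cohen's
d = (M_a − M_b)/√MSE, p-values unadjusted by construction.  The report
pipeline runs the planned test-1 analyses (one ANOVA per list
organization); the omnibus 2 × 3 × 3 mixed ANOVA is deliberately not
reimplemented — standard repeated-measures software covers it.  The ARC
follow-up contrast (item-JOL vs no-JOL, randomized lists, test 1) is a
one-tailed Student's pooled-variance t test.

ARC is computed per participant per test; the report analyzes test 1 by
default, where the planned contrast lives.

## Problem sizes used in the validation suites

The packaged suites validate at sizes chosen to make Monte-Carlo error
small relative to the tolerances they assert: pattern-probability
normalization and oracle equivalence at 10⁴/10³ random parameter
vectors; the E(R) permutation oracle at 100 compositions × 10⁵ shuffles
(z-scores bounded as standard normals); parameter-recovery bias (< 0.02)
at 200 replicates × 4,000 items; ΔG² type-I calibration at 2,000 null
replicates of 320 items per condition under the interior truth described
above; and the end-to-end seeded-J₁ detection at 40 participants per
cell.
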