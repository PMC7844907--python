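# Methods

## Setting and model

The package implements the validation analysis of an 11-item child
depression screener administered to 296 children aged 7–14 living with
HIV, each of whom also received a gold-standard structured clinical
interview (42 interview-positive, 254 negative). Items are scored 0–3
(symptom absent → always present); the instrument total is the
unweighted sum, range 0–33; a child screens positive at `total >= cutoff`.

The aggregation rule deserves a note: published material on the
instrument specifies the items and answer scale but not the aggregation.
An unweighted sum is the simplest rule consistent with the reported
cutoff analysis (cutoffs 4–10 all attainable on a 0–33 range), so it is
the package's rule; no item carries special weight and no single item
(e.g. suicidality) forces positivity. Likewise "screen-positive" is
taken as *score at or above* the cutoff, applied consistently everywhere
including the reconstruction arithmetic, which is self-confirming: with
the ≥ convention the printed table inverts to a unique integer solution.

Missing item values are an error by default. An opt-in proration mode
(rescale the sum of answered items to 11 items, round half-up, at most
2 missing) exists for field use but is never exercised by the validation
pipeline.

## Diagnostic accuracy

Per cutoff: TP/FP/FN/TN, Se, Sp, PPV, NPV, balanced accuracy (Se+Sp)/2.
Ratios with zero denominators are reported as an explicit undefined
marker (`None`), not zero and not an exception, because degenerate cells
are routine at sweep extremes. Two "AUC" notions are kept strictly
apart: the per-cutoff balanced accuracy (what per-cutoff "AUC" columns
of screening tables report — it equals the area of the one-point ROC
polygon) and the empirical trapezoidal AUC of the full integer-threshold
sweep (thresholds 34 down to 0), which equals the Mann–Whitney pair
statistic with ties weighted ½. The optimal cutoff maximises balanced
accuracy; ties break toward the larger cutoff, preferring the more
specific screen so scarce referral capacity is protected.

## Rounding inversion

A percentage printed to *d* decimals pins its numerator to the set
`{k : |100k/n − printed| ≤ 0.5·10⁻ᵈ + 1e−9}`. The epsilon guards
against binary-representation edge cases; the printed values are treated
as half-up rounded (e.g. 99.606 → 99.6). Per cutoff row, a candidate
(TP, FP) must *jointly* re-round to the printed Se, Sp, PPV, NPV and
balanced-accuracy cells — single cells are often ambiguous; the joint
system plus monotonicity of exceedance counts across cutoffs is what
forces uniqueness. Inconsistency (no solution) and ambiguity (several)
are distinct, loudly reported error states naming the offending cutoff,
so the module doubles as an audit tool for published tables. The same
inversion applied to the demographic table recovers the depressed count
per province, age band and sex; the three partitions independently sum
to the same 42 positives — a strong internal-consistency check the
published numbers pass.

Differencing the exceedance profile yields per-group score histograms at
the resolution the table determines: one open bin below 4, exact counts
for 4–9, one open bin at ≥10.

## Synthetic cohort generator

The generator emulates exactly what the publication fixes and nothing
more. Constrained quantities — group sizes, binned score counts,
demographic margins, and the province/age-band/sex cross-classifications
with depression — are allocated as fixed integer counts and seeded
shuffles, so they are matched *exactly*, not in expectation. Only
unconstrained detail consumes randomness: placement inside the open bins
(uniform over 0–3 below; truncated geometric with ratio 0.6 over 10–33
above — arbitrary but documented, and provably irrelevant to every
cutoff-4–10 statistic since those scores never cross the table's range),
uniform item-level decomposition of each total (sequential conditional
sampling with exact composition counts), age within band (uniform by
default; a calibrated mode reweights within bands to approach the
published mean of 12, SD 1.9), and the pairing of demographics not
linked to depression in the source (residence, education, caregiver,
disclosure, ART duration, viral suppression), which are assigned
independently of depression status given their margins. An optional
facility layer (2 urban + 3 rural sites per province) adds realism but
feeds no statistic.

Three demographic margins are published with counts that do not sum to
296 (education 292, disclosure 285, viral load 261 — item non-response);
their cohort margins are rebuilt from the printed percentages by
largest-remainder apportionment over 296. These variables enter no
validation statistic.

Consequences for interpretation: passing tests show the *pipeline*
recovers every quantity the published tables determine, exactly and
deterministically. They do not show anything about item-level response
patterns, within-band score shapes, or correlations among demographics —
the source contains no information on those, and the generator makes no
claim to realism there.

## Prevalence and comparisons

Prevalence is k/n with Wilson score intervals by default (deff enters
via the effective sample size n/deff, keeping the interval inside
[0, 1]); a logit-scale interval (SE inflated by √deff; undefined at
k ∈ {0, n}) and exact Clopper–Pearson (no variance parameter, so deff is
ignored with a warning) are alternatives. Bounds are clamped to [0, 1]
and to contain the point estimate, guarding against float round-off at
the boundaries. The published overall interval (9.6–20.4% around 14.2%)
matches none of these constructions even at deff 1.2 — it presumably
reflects cluster-level survey structure unavailable in the summary
tables — so only point estimates are claimed exact. Subgroup contrasts
use the Pearson chi-square test without continuity correction and report
the 2×2 odds ratio; zero-margin tables return undefined markers.

## Sample size

Buderer's formula with the exact normal quantile (1.959964…, not 1.96;
both give the same integer here, but exactness keeps implementations
deterministic). The study's 283 arises from A = 0.90, d = 0.07,
p = 0.25 with *no* design-effect, non-response or finite-population
terms; those adjustments exist as a separate composable step
(multiply by deff → FPC n/(1+(n−1)/N) → divide by 1−non-response →
ceiling once at the end). Two documented oddities: the study text
mentions a design effect of 1.2 alongside 283, but 283 = ⌈282.24⌉ is
attainable only without it; and the text says "expected specificity"
while the denominator matches the sensitivity-style d²·p with p the
depression prevalence. The package reproduces the printed number and
records the discrepancy rather than resolving it.

## Problem sizes and determinism

Everything is desk-scale by design: table inversion is an exhaustive
search over ≤ 300 numerators per cell (milliseconds), cohorts are 296
records, ROC sweeps 35 thresholds, and the test suite's property checks
use cohorts of ≤ 500 records, where the brute-force pair-counting AUC
oracle is exact and fast. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
cohort CSVs, and every cutoff-range statistic is invariant to the seed
altogether.

## Known limitations

- Item-level structure is synthetic: uniform over compositions, with no
  inter-item correlation or severity gradient.
- Only the province/age/sex × depression joints are identifiable from
  the source; all other demographics are independent of depression by
  construction, so the cohort cannot support adjusted-accuracy analyses.
- Confidence intervals for the published subgroup prevalences are not
  reproduced (construction unreported); the package's intervals are its
  own, documented constructions.
- The screener's measurement properties (reliability, item response
  theory, measurement invariance) are out of scope; the package treats
  the instrument as given.
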