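# Methods

## The model and its assumptions

The unit of observation is a football match between one of a small set of
focal ("head") clubs and an opponent club, with the number of
police-recorded hooligan incidents around that match as the response.
Incidents are aggregated at club level: a declared-alliance registry may
name individual organised fan bases, but all statistics are computed on the
clubs they attach to.

Every inferential statement reduces to one primitive: an unequal-variance
(Welch) comparison of a club pair's per-match incident mean against a
pooled benchmark — the per-match incident distribution across all club
pairs in scope, heads included. The statistic is

    U = (x̄_pair − x̄_bench) / sqrt(s²_pair/n_pair + s²_bench/n_bench)

referred to a t distribution. A pair significantly above the benchmark is
labelled a *rivalry*, significantly below an *alliance*, otherwise
*undefined*. Step one applies this to head pairs; step two to every
(head, third club) pair. The triple of labels — head pair plus the two
components — classifies the affinity of two heads and a third club:

| head pair | both components | class |
| --- | --- | --- |
| alliance | rivalry | coup (friends with a mutual enemy) |
| alliance | alliance | peer (friends with a mutual friend) |
| rivalry | rivalry | clash (enemies with a mutual enemy) |
| rivalry | alliance | split (enemies with a mutual friend) |

Any other combination, including any undefined input, is an undefined
affinity — a valid outcome, not an error.

The transitive friend/enemy expectation for each tested interaction comes
from the declared registry: a direct declaration wins; otherwise one-hop
composition through a head (friend of friend = friend, friend of enemy =
enemy, and so on), with conflicting paths treated as inconclusive. A
*supports* verdict means the observed label matches the expectation
(declared-friend side observed as alliance, enemy side as rivalry);
*contradicts* means the opposite label was significant; everything else is
*inconclusive*.

Implicit assumptions worth keeping in view: per-match counts within a pair
are treated as i.i.d. (no season, venue or policing covariates); the
benchmark is treated as an independent reference even though it pools the
tested pair's own matches; and the t reference distribution presumes the
pair mean is approximately normal, which is questionable at the observed
sample sizes (see *Calibration* below).

## Degrees of freedom, sidedness, and degenerate rows

Two df rules are implemented: the Welch–Satterthwaite fractional
approximation (default) and the additive rule (n₁−1)+(n₂−1). The default
is Welch–Satterthwaite with a **one-tailed** p in the direction of the
observed difference because that convention exactly reproduces the
published second-step table from its own printed means and SDs; the
additive rule and a two-tailed option remain available by configuration.

The p-value is undefined (reported as missing, mirroring the published
dashes) whenever the pair sample has fewer than two matches or zero
variance. The zero-variance case matters: all-zero pairs are kept in the
data (mean 0, SD 0) but yield no test, rather than a spuriously enormous
|t| against the benchmark's variance alone. "No matches at all" is a
distinct state from "matches with zero incidents".

Significance uses two tiers — strong below 0.05, weak in [0.05, 0.1) —
with both thresholds configurable. No multiplicity correction is applied
by default, matching the procedure as published across its 15 club tests;
a Holm-adjusted column can be requested and is reported separately, never
silently substituted.

An analyst can override a head-pair relation (an `AssumedRelation`),
which is tracked with `assumed` provenance end to end. The published coup
instance requires exactly this: the two non-focal heads test as undefined
but are circumstantially treated as friends.

## Reconstruction of printed rows

Printed (mean, sample SD) rows are inverted by exhaustive search: for each
candidate n from 2 upward, the mean constrains the integer sum to a short
interval, the SD then constrains the integer sum of squares, and a
backtracking enumeration over non-decreasing non-negative integer vectors
(entries ≤ 40 by default) checks realisability. The first n admitting a
solution is returned with all solutions at that n; the lexicographically
smallest is canonical. Only (n, mean, SD) feed the test, so the choice
among ties is immaterial.

Matching conventions are explicit per value: *exact* (a printed "1" or
"2.75" taken as the true value), *round* (round-half-away-from-zero at the
printed decimals), or *trunc* (truncation — some published values are
demonstrably truncated, e.g. a printed mean of 1.66 for 5/3). The
convention matters: an SD of 0.707107 with a printed mean of "1" resolves
to n = 5, counts {0,1,1,1,2}, whereas rounding would accept the n = 2
vector {0,1} whose mean 0.5 also rounds to 1.

Two published rows (printed p 0.257332 and 0.123865) are inconsistent
with every integer reconstruction of their own printed means and SDs; the
fixture keeps their reconstructed counts and reports the recomputed
p-values (0.2737 and 0.2096). Both sit far from the 0.1 boundary, so no
headline count changes. The head-pair (step-one) table is *not*
recomputed at all: its benchmark group is underdetermined in the source
(the stated aggregate mean of 8.064 incidents/match conflicts with the
stated totals of 1363 incidents in 374 matches), so step-one results are
carried as printed labels, and the benchmark scope is a configuration
knob rather than a guess.

## The network representation

Nodes are clubs with at least one recorded incident against a head; edges
connect a head to each such club. Node size is an affine map of
log(1 + total incidents) onto a configured range — the log keeps the
heavy-tailed totals from swamping the scale, and only the size *ordering*
is contractual. Edge "length" is rendered as 1/(1 + incident sum):
hostile pairs sit close. Each head anchors a 1-based cluster; a club joins
the cluster of the head it shares the most incidents with (ties broken by
head order).

The per-edge *relevance score* is defined here as the head-conditional
incident share (edge incidents / head total), so a head's scores sum to 1
and the top score marks the opponent most likely to co-occur in violence
with that head. The source article cites such a score without printing a
formula; this definition is an interpretation and is labelled as such in
outputs.

The circular layout places heads on an inner circle with angular gaps
shrinking in rivalry grade, and each opponent on one of two outer rings at
the angle of a softmax-weighted blend of its adjacent heads' positions
(weights from the affinity statistics). This guarantees the two
contractual properties — a club with the larger affinity statistic toward
head *a* lands strictly nearer *a*, and equal statistics give equidistant
placement — and is fully deterministic. Pixel-level reproduction of the
published figures is out of scope.

Exports: a documented Pajek dialect (`.net` vertices with sizes and edges
with weights, `.clu` 1-based partition; byte-identical under
export → import → export), GraphML with all attributes, and an edge-list
CSV.

## The synthetic generator

The generator emulates the observed regime, not any particular dataset:
3 head clubs, 24 opponents, every head–head and head–opponent pair
scheduled, 5 matches per pair (about 375 matches, matching the reported
374 over roughly 80 pairs), and per-match counts from a negative binomial
with mean 2.28 and shape r = 0.4, chosen so the marginal SD (≈3.9)
matches the published pooled SD of 3.92 against a mean of 2.28. The shape
value is an emulation choice — the source reports no dispersion estimate —
and a Poisson option exists for limit checks.

A planted rate ratio ρ acts by superposition: the pair draws
NB(shape = rρ, mean = 2.28ρ), i.e. a rivalry match behaves like the
aggregation of ρ baseline-like conflict processes (the NB family is closed
under such aggregation, and the variance-to-mean ratio stays stable across
effect sizes). Ratios above 1 plant rivalries, below 1 alliances.
Randomness flows from a single master seed through per-replicate
`SeedSequence` streams; identical configurations produce byte-identical
datasets.

What the generator does *not* emulate: temporal structure (derby dates,
season phases), venue effects, correlated policing intensity, and
reporting artifacts. Tests passing on synthetic data therefore validate
the pipeline's statistical behaviour under the stated count law, not the
sociology of any real fixture list.

## Calibration findings

`run_calibration` measures size and power by replication. The size
measurement uses the two-tailed p so that the nominal level of the
"is this pair non-neutral?" decision equals α (the directional one-tailed
convention doubles it); sidedness is configurable. A leave-one-pair-out
benchmark removes the tested pair's own contamination of the pooled
reference; the contaminated (pooled) variant is also available so the bias
can be exhibited rather than silently fixed.

The central finding, reproduced by the test suite at its design point
(all-neutral planting, 30 matches per pair, leave-one-pair-out benchmark,
2000 replicates): the empirical rejection rate at α = 0.05 is ≈0.10, about
twice nominal, and the excess does **not** come from benchmark
contamination. It comes from the count distribution itself: with strongly
overdispersed counts, low-count samples pair a small mean with a small SD,
inflating |t| on the alliance side. The size only approaches nominal at
around 100+ matches per pair — outside the regime of real per-pair
schedules (2 to a few dozen matches). Practically, weakly significant
"alliance" findings from this procedure should be read with skepticism;
the package reports this property instead of papering over it, and the
corresponding null p-value distribution is checked against uniformity only
up to a documented Kolmogorov–Smirnov tolerance of 0.12. Power, by
contrast, is excellent where it should be: a planted rate-ratio-5 rivalry
at 30 matches per pair is recovered in well over 90% of replicates.

## Numerical and design choices

- Sample SD uses the n−1 denominator throughout and is undefined at n = 1.
- Reconstruction-search bounds default to n ≤ 40, counts ≤ 40 — far above
  any published row — and are configurable.
- Benchmark scope is configurable (all matches, a named club subset, or an
  explicit (n, mean, SD) triple) because the published analysis evidently
  used different benchmark groups in its two steps.
- The fixture's declared registry is synthetic: the source's appendix
  registry is not reproduced in the available text, so the registry is
  constructed to be consistent with every narrative statement of the
  results (which side each partner was declared on, which interactions
  supported or contradicted the expectation). It is documented as such in
  its module.
- Tie-breaks are deterministic everywhere (head order for cluster ties,
  lexicographic order for reconstruction ties, sorted node order in
  exports), so every artifact is reproducible bit-for-bit.

## Known limitations

- Step-one p-values cannot be validated against the source (benchmark
  underdetermined); only the label logic is validated.
- The relevance score and the registry are interpretations, clearly
  flagged, not recovered source artifacts.
- The procedure's anti-conservatism under overdispersion is reported, not
  corrected; a count-model alternative (e.g. negative-binomial regression
  with offsets) is deliberately out of scope, as the aim is to
  operationalise and audit the published procedure, not replace it.
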