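# Methods

This note records the models, conventions and numerical choices behind
`reosig`, in the order the pipeline uses them, plus what the synthetic
cohorts do and do not emulate.

## Evaluability conventions

Every ordering-based quantity in the package shares one rule set:

* a pair is **not evaluable** in a sample when either gene is unmeasured
  (NaN) or both measurements are exactly zero;
* a pair with exactly one zero **is** evaluable — zero is a measured
  abundance, and "0 < x" is a usable ordering in a degraded profile;
* equal nonzero values are an evaluable **tie**; a tie never matches a
  directed pattern (orderings are strict), so ties count against pattern
  frequencies and retention rates but stay in the denominator.

Missing-vs-zero is preserved end to end: empty cells in input tables,
genes absent from a dataset after universe harmonization, and unmeasured
genes in a single profile all become NaN, never 0.

## Stable and significant opposite pairs

Stability thresholds are inclusive (`freq ≥ threshold`) and require at
least one evaluable sample; thresholds at or below 0.5 are rejected because
the majority orientation would be ambiguous. Each unordered pair is emitted
at most once, oriented to its majority (or reference-group) direction.

The reversal test for significant opposite pairs pools the two groups'
evaluable samples and conditions on the total reversal count; the p-value is
the cumulative hypergeometric tail for the reversal count in the
non-reference group (`opposite_pair_pvalue`, equivalent to a one-sided
Fisher tail on the 2×2 group × direction table). Because the pair's
orientation is itself chosen as the reference group's majority direction —
a data-dependent choice — `find_significant_opposite_pairs` doubles the
one-sided tail (a union bound over the two orientations) before
Benjamini–Hochberg adjustment. Without the doubling the test is
anti-conservative under label permutation (measured false-discovery
proportion ≈ 0.10 at nominal 0.05); with it the null FDP is controlled
(≈ 0.02 measured over 50 permutation seeds). BH adjustment delegates to
statsmodels throughout.

## Diagnosis signature

Candidates are stable opposite pairs between training tumours and normals
at the 99% threshold. avgRD is computed as `sqrt(|mean_c| · |mean_n|)` of
the signed within-sample rank differences; group means run over the samples
where both genes are measured. The square root is a monotone transform of
the product, so candidate ranking — and therefore the greedy redundancy
removal — is identical under either reading; the geometric-mean form is
used because it is the operational definition. Redundancy removal scans in
descending avgRD with lexicographic (gene_a, gene_b) tie-breaks for
determinism; all surviving pairs form the signature (no fixed size). The
vote is inclusive: retention ratio ≥ 60% calls CRC. A sample in which no
signature pair is evaluable is labelled `not_evaluable` rather than forced
into a class, and counts as incorrect in accuracy tables.

## Rank-disruption DEG caller

A deliberately single-pass dialect of rank-comparison differential
expression: (1) exact binomial stable pairs within each group
(one-sided tail against p = 1/2, BH, FDR < 20%); (2) the partner universe
is the intersection of the two stable-pair lists; (3) per gene, the 2×2
table of partners ordered below/above it in each group is tested with a
two-sided Fisher exact test (BH, FDR < 5%); direction is `up` when the
fraction of partners below the gene rises in the second group. No iterative
re-estimation rounds are performed — disruptions are assessed once against
the jointly stable background.

## Relapse signature

Candidates are significant opposite pairs between stage IV and stage I
tumours (FDR < 0.01, stage-IV pattern as reference) restricted to pairs
containing at least one DEG. The paired FF/FFPE filter counts sample pairs
in which the ordering is evaluable in both preservation states and
identical between them (a tie in either member does not count as keeping a
directed pattern); gene pairs need ≥ 10 concordant sample pairs by default.
Survivors are ranked by signed C_IVI (descending; ties by descending
stage-IV coverage, then genes) and partitioned into blocks of
3500 + 1000·(n−1) pairs with the remainder as the final block. Selection
evaluates each block at cut-offs {49%, 50%, 51%}: the cut-off maximizing
mean stage-IV accuracy is chosen (ties towards the smallest), and among
blocks with both stage accuracies above 80% the one with the most pairs
wins (robustness through redundancy); if none passes, the block with the
best worst-stage accuracy is returned with a warning. The relapse vote is
strict (`ratio > cut-off`), unlike the diagnosis vote.

## Survival evaluation

All estimators wrap lifelines: Kaplan–Meier product-limit curves, the
two-group log-rank test (no events in either group returns p = 1), Cox
partial-likelihood fits with the Efron tie approximation and Wald 95% CIs
from the observed information, and the Schoenfeld-residual test using the
event-time **rank** transform (requires ≥ 3 events; non-convergent fits are
flagged, not raised). Fixed-horizon analyses (3-year/5-year) use
administrative censoring: events after the horizon become censored
observations at the horizon. Records with missing covariates are dropped
from multivariable fits and counted in the fit summary.

## Synthetic cohorts

Expression is log-normal (heavy-tailed, FPKM-like; the exact family is
immaterial to rank-based methods). Defaults: 300 genes; 40 normals, 20 IBD,
40/20/20/40 stage I–IV tumours; per-measurement log-noise sd 0.2; cohort
dropout rate 0.3.

* **Planted diagnosis pairs** (default 12): two log-levels, centre ± 0.5,
  that swap between normal-like and cancer samples. Centres sit on a grid
  spaced 2.4× the half-gap and background gene means are rejection-sampled
  outside windows of ± 1.1× the half-gap around each centre, so that on
  noise-free data the stable opposite pairs are *exactly* the planted ones
  (no incidental reversals from genes crossing a swapped level). IBD
  profiles are the normal profile plus a ± 0.01 per-gene jitter — far
  smaller than any planted gap, so colitis never acquires the cancer
  pattern.
* **Planted relapse pairs / DEGs** (default 30): each relapse gene swings
  between centre ± 1.5 with per-sample Bernoulli probability
  (1−gap)/2 = 0.2 in stage I and latent low-risk II/III tumours versus
  (1+gap)/2 = 0.8 in stage IV and latent high-risk tumours; its partner
  sits at the centre, so the pair's coverage difference equals the
  configured gap (0.6) in expectation. The swing also disrupts the gene's
  orderings against every background gene inside its window — making it a
  genuine rank-shift DEG. The centre and both swing states are kept clear
  of the diagnosis windows (a constant gene inside a swapped window would
  otherwise create an unplanted stable opposite pair).
* **FFPE degradation**: each nonzero value is zeroed with probability
  `sigmoid(bias · (threshold − log x))` (default bias 6 — dropout strongly
  prefers low expression, as degradation does), with the threshold
  calibrated by bisection so the realized zero fraction matches the
  requested rate; survivors get multiplicative log-normal noise. Paired
  FF/FFPE samples are clean stage II–IV columns and their degraded copies
  (default 13 pairs, 35% zeros, log-noise 0.5).
* **Purity**: cancer columns can be convex mixtures with the noise-free
  normal consensus. The default leaves training tumours unmixed
  (signatures are discovered on research-grade resections; purity mixing
  characterizes *application* samples), and `mix_purity` builds low-purity
  profiles explicitly — planted orderings survive any tumour fraction
  above one half.
* **Survival**: exponential event times (baseline hazard 0.02/month, true
  HR 3 for latent high-risk), censored by independent per-subject
  exponentials with rate `hazard · q/(1−q)`, which makes the expected
  censored fraction exactly q (default 0.2) in both groups.

Everything is driven by one `numpy` Generator seeded from the config, so a
cohort is bit-reproducible.

What the generator does **not** emulate: read-level sampling noise,
library-size or GC effects, cross-platform batch effects, gene–gene
correlation beyond the planted structure, RIN-dependent 3' bias, or
competing risks. Passing recovery tests therefore demonstrate that the
algorithms recover the structure they assume under zero-inflation, noise
and purity mixing — not that real cohorts contain that structure.

## Problem sizes and test design

Property and acceptance tests run at desk scale chosen by the package:
300-gene universes, 40 samples per group, 10 seeds for recovery, 50
permutation seeds for FDR calibration, 1000 simulations for log-rank
type-I error, and 200 replicates for Cox CI coverage. The exact tests
(hypergeometric reversal tail, binomial stability tail, Fisher DEG test)
are verified against exhaustive rational-arithmetic enumeration on all
group sizes ≤ 12 to 1e-10. Cox CI coverage at n = 500 with HR = 3 is
asserted in [0.90, 0.985]: the Wald interval's true coverage on this design
is ≈ 0.94 (cross-checked against an independent proportional-hazards
implementation), and 200 replicates carry ± 3% Monte Carlo width. The full
pair scan is guarded by a configurable gene cap (default 3000) because the
candidate universe grows quadratically; pass an explicit candidate list or
raise the cap deliberately for larger universes.
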