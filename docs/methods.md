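# Methods

## The measurement model

A population of cells is arrested in G1, sampled, released into 200 mM HU,
and sampled again in early S. Sequencing coverage of the G1 sample is uniform
at copy 1; in the S sample, a position `x` has been replicated only in the
fraction of cells whose forks reached it, so its expected copy number is
between 1 and 2. With each sample normalized to its own total read count, the
per-bin ratio

    r(x) = S_norm(x) / G1_norm(x) = c(x) / c̄,   c̄ = genome-mean copy

is the *relative* copy number: total-read normalization makes a uniform
global copy change invisible (a property the test suite asserts exactly), so
all information is in the shape of the profile, not its absolute level. This
is why per-origin scores sit slightly above 1 at active origins and slightly
below 1 in unreplicated regions, and why a ×1.25 presentation scaling is
conventional for scatter plots of early-S data: it compensates for the
genome-mean progression during the arrest. The scaling is cosmetic and the
package never lets it reach RFOF or activation scores.

## Pipeline stages and their conventions

**Binning** (250 bp default). All coordinates are 0-based half-open; bin `k`
covers `[k·250, (k+1)·250)`, the last bin may be short. Two counting modes:
*midpoint* (a fragment goes to the single bin containing
`floor((start+end−1)/2)`; totals exactly conserve fragment count) and
*overlap* (every bin intersected by ≥1 bp is incremented, compatible with
`bedtools multicov`). Midpoint is the default because exact conservation
makes downstream algebra testable; both agree with a per-base brute-force
counter in the suite. Mate pairs are not merged — callers pass either read
or fragment intervals.

**Ratio track.** Bins with zero G1 coverage are masked with a recorded reason
(`zero_G1` / `zero_both`) and excluded from every downstream mean; no
imputation. BedGraph serialization drops masked bins and round-trips
unmasked values to 6 decimals.

**Origin scores.** OriDB-style coordinates are treated as 1-based inclusive;
the midpoint is `floor((start−1+end)/2)` after conversion. The relative copy
number is the overlap-weighted mean of unmasked bins over
`[midpoint − w/2, midpoint + w/2)` with `w = 1000` bp; partial bins weigh by
their bp of overlap (the window need not align to the grid). If less than
50% of the window's bp is unmasked the score is undefined rather than
dominated by one bin. Subtelomeric origins (X/Y′ elements, not uniquely
mappable) are excluded either by an explicit name list or by a
midpoint-to-chromosome-end margin; both mechanisms are provided because the
appropriate one depends on the annotation at hand.

**RFOF and the signed-rank test.** RFOF is `(mutant − WT) × 100` per shared,
unmasked origin. The one-sided Wilcoxon signed-rank test (alternative: true
median > 0) drops zeros, assigns average ranks to ties, and uses the exact
null distribution of `W+` (dynamic programming over doubled ranks, so ties
are handled exactly) for `n ≤ 25`; beyond that, a normal approximation with
continuity correction and tie-corrected variance. The p-value is
`P(W+ ≥ observed)`, matching R's `wilcox.test`; the suite cross-checks the
exact branch against full 2ⁿ enumeration and against `scipy.stats.wilcoxon`
on tie-free data.

**Activation score.** With `q = score(target)/score(reference)` per strain
(defaults ARS608/ARS607), the score is `(q_mut − q_WT) × 100`
(`subtract_x100`, the default — the same normalization arithmetic as RFOF) or
`q_mut / q_WT` (`ratio`). The published description of this statistic is
ambiguous between the two; both are implemented and the mode is recorded in
the output so results are never silently mode-dependent.

## The simulator

Each origin `i` fires independently per cell with probability `f_i`. A fired
origin replicates `[m_i − D, m_i + D]` with `D ~ Normal(μ, σ)` truncated at 0
(point mass at `μ` when `σ = 0`); a position is replicated if any origin
reached it, giving

    c(x) = 1 + (1 − Π_i (1 − f_i · q_i(x))),   q_i(x) = P(D ≥ |x − m_i|).

Read counts are Poisson per bin with rate ∝ copy × bin width, scaled to the
sample's expected depth; G1 and S use independent substreams of one master
seed. A per-cell mode (explicit Bernoulli firing and sampled distances per
cell) is the stochastic oracle for the closed form. Defaults: depth 10⁶
fragments/sample, 10⁴ cells in per-cell mode, fork travel μ = 6000 bp,
σ = 1000 bp. The true fork-travel distance under 200 mM HU is not well
constrained; 5–10 kb is the plausible range and 6 kb is a placeholder within
it, not a measured value.

Deliberate simplifications: forks travel the same sampled distance in both
directions; no fork merging beyond the union rule; no passive-replication
timing; Poisson (not negative-binomial) counts, since clonal-arrest WGS
coverage at 250 bp is near-Poisson; no sequence-level simulation, no
mappability structure. Consequently, passing tests demonstrate the
*statistical* correctness of the pipeline under the stated model — they say
nothing about alignment artifacts, GC bias, or repeat mappability in real
data, which upstream processing must handle.

The `two_strain_default` fixture is a 300 kb two-chromosome toy genome with
an efficient early origin (ARS607-like, f = 0.9) 12 kb from a dormant origin
(ARS608-like, f = 0.1 in WT vs 0.7 in the mutant) plus interior origins,
echoing the chromosome VI-right geometry at reduced scale; `ars_toy` is the
minimal pair; `edge_cases` exercises window truncation at chromosome ends
and status filtering.

## Estimating a firing fraction

At an isolated origin, every position its forks almost surely reach has
expected ratio `(1 + f)/c̄`, so `f̂ = r·c̄ − 1`. The estimator averages `r`
over the plateau of half-width `μ − 3σ` (at least 500 bp) rather than a
fixed 1 kb: under the fork model all those bins carry the same information
about `f`, and using them shrinks the sampling error (bias from the plateau
approximation is < 0.002 at the default parameters, against a sampling sd of
~0.01–0.02 at depth 10⁶ on the fixture genome). `c̄` is taken from the known
simulation parameters; on real data it would need an external estimate of
S-phase progression. The estimator is only valid where no other origin's
forks plausibly reach the window.

## Numerical and design notes

- Chromosome names are canonicalized through an alias table
  (`chrVI`/`VI`/`chr6`/`6`); unknown names are errors, never silent drops.
- A window mean is undefined (NaN) below 50% unmasked coverage; NaN scores
  propagate to RFOF/activation as dropped origins or explicit errors, never
  as silent zeros.
- Heatmap rows keep annotation order by default; `sort_by` re-orders by an
  external key (e.g. WT score) since figure orderings are a presentation
  choice.
- Under the default fork model the ratio profile is flat to ~10⁻⁶ within
  ±(μ − 3σ) of a midpoint, so the argmax of a noisy heatmap row is not a
  meaningful localization statistic; localization is asserted on the
  noise-free profile, where the maximum is strictly at the center column.
- Problem sizes in the validation study (100 random ≤ 5 kb genomes for the
  binning oracle, 200 datasets of n ≤ 10 for the Wilcoxon enumeration, depth
  10⁶ with ten seeds for parameter recovery) were chosen so each check's
  Monte-Carlo error is far below the tolerance it asserts while the whole
  study runs in seconds.

## Known limitations

- No GC-bias or mappability correction; subtelomeric exclusion is the only
  repeat handling, as in the standard analysis.
- The activation-score normalization ambiguity (subtract vs ratio) is
  surfaced, not resolved; published scores computed with an unknown mode
  cannot be compared across modes.
- `f̂` requires the genome-mean copy `c̄`, which is exactly known only in
  simulation.
- The signed-rank normal approximation is used above n = 25; for the ~300
  confirmed origins of a real genome this is the relevant branch and its
  continuity/tie corrections match standard statistical software.
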