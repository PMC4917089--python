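# Methods

## Design and scope

The package analyses a five-library, unreplicated tag-count design: two F1
hybrids (AC, BC) sharing a paternal inbred (CC), plus the two maternal
inbreds (AA, BB). Each library is a pooled sample (biological replicates
mixed before sequencing), so there is no replicate variance to estimate;
the statistical model treats tag sampling as the only noise source. The
pipeline starts from per-gene integer counts — tag extraction, read
cleaning and genome mapping are upstream of it.

## Normalization

TPM is defined against raw library totals: `tpm = k / N * 1e6`. A gene is
*expressed* in a library iff TPM > 1, strictly; a gene enters a pairwise
test iff expressed in at least one of the two libraries compared. The
filter is applied to raw TPM, before any scaling adjustment: TPM is defined
per million *clean tags*, so effective sizes alter tests only, never the
TPM values or the expressed mask. (Whether filtering precedes scaling is a
genuinely open choice; this order is the package's documented one.)

One TMM scaling factor per library is computed against a reference library
(default the shared paternal CC, the anchor of every trio comparison). The
algorithm follows the edgeR reference implementation of the trimmed mean of
M-values: genes with a zero count in either library are dropped; genes in
the top/bottom `trim_m` = 0.30 rank quantiles of M = log2 proportion ratio
or `trim_a` = 0.05 quantiles of A = mean log2 proportion are removed
(average ranks for ties); the factor is 2 to the inverse-variance weighted
mean of the surviving M values, with approximate variances
`1/k_t - 1/N_t + 1/k_r - 1/N_r`. A library against itself returns exactly
1. Because the weights depend on absolute counts, the factor is scale-free
only up to the weighting approximation (observed shifts ~1e-3 when a
library is rescaled); the unit tests assert this as an approximate, not
exact, invariance. Fewer than 10 surviving genes raises an error advising
`scaling=False`, which forces all factors to 1.

## Exact tests

*Pairwise:* conditional on `t = k_a + k_b`, the null is
`k_a ~ Binomial(t, p0)`, `p0 = N_a_eff / (N_a_eff + N_b_eff)`. Two-sided
p-values use the minimum-likelihood rule (sum of all outcome probabilities
not exceeding the observed one), which calibrates better on discrete counts
than tail-doubling. A relative tie guard of 1e-7 on pmf comparisons absorbs
floating-point ties, the same convention scipy's binomtest uses. The
implementation enumerates the probability-bearing support (a window of
±50 SD around the mode; outside it the pmf underflows double precision)
with a bisection/incomplete-beta fallback for supports too wide to
enumerate. The log2 ratio carries a 0.5 pseudocount — in the ratio only,
never in the test — so it is finite at zero counts.

*Mid-parent:* under additive gene action the hybrid expression equals the
parental mean, so the null is `k_h ~ Binomial(round(N_h_eff), p0)` with
`p0 = (p_m + p_p) / 2` and equal parental weights (the genetic definition
of the mid-parent value). Parental proportions are taken on the effective
scale (`k / N_eff`), not raw TPM, so the mid-parent test shares the
calibration of the pairwise tests; this is the package's choice where the
alternative (raw-TPM proportions against an effective-size denominator)
would mix scales. The null is plug-in: parental sampling noise is ignored,
which inflates the rejection rate of truly additive genes to roughly 2x
the nominal level (the parental estimate contributes half the hybrid's
variance). `p0 = 0` with a nonzero hybrid count returns p = 0, direction
up (hybrid-only expression), not an error.

*Multiple testing:* Benjamini–Hochberg step-up, families per comparison:
each pairwise comparison's expressed-in-either gene family; the mid-parent
p-values form their own family over each hybrid's trio DEGs. Significance
means adjusted p < alpha = 0.05, strict.

## Trio DEG calling and classification

A gene is a trio DEG iff both hybrid-vs-CC calls are significant and
concordant and the hybrids are ranked by TPM (`AC > BC` for the up class,
`AC < BC` for down). Discordant genes are excluded. The AC-vs-BC test is
*not* required to be significant by default — requiring it would break the
partition of concordant DEGs into exactly two monotone classes;
`strict_trio=True` adds the requirement.

Classification per hybrid is a fixed decision tree: (1) mid-parent call not
significant → additive; (2) significantly above both parents →
over-dominance; (3) below both → under-dominance; (4) not different from
the maternal parent and different from the paternal → maternal-ELD;
(5) the mirror case → paternal-ELD; (6) otherwise other-nonadditive.
"Equal to one parent" is operationalized as failure to reject at the
BH-adjusted level — absence of evidence, as is standard in the
expression-pattern literature. Because the hybrid-vs-paternal call is the
same comparison trio membership already requires to be significant,
paternal-ELD is structurally unreachable for trio DEGs; the branch exists
for completeness. A trio gene absent from a parent comparison's family
(not expressed in either library of that pair) counts as not significant
there.

All reported percentages are re-derived from counts at render time with
half-up two-decimal rounding: non-additive shares over the trio DEG total,
category shares over that direction's non-additive count, and the
maternal-ELD fold ratio as the larger hybrid total over the smaller. Zero
denominators render as undefined, never as 0.

## GO enrichment

Hypergeometric upper tail `P(X >= k)` of study hits among an
expressed-gene background (union of the >1 TPM masks; configurable). BH is
applied within each ontology separately (configurable to one pooled
family); a term is enriched iff p < 0.05 *and* FDR < 0.1, both strict.
Annotations are used exactly as supplied — no GO-graph ancestor
propagation; users may pre-propagate.

## Synthetic data

The generator emulates the study conditions: five libraries of ~10^6 tags,
Poisson noise (pooling replicates before sequencing leaves no replicate
variance; a negative-binomial option exists for robustness studies), and a
log-normal baseline (sigma = 0.5 in natural log) normalized so baseline
TPMs sum to 1e6. The default 2,000 genes is the scale the recovery and
calibration analyses run at; the gene count is a parameter and the study
scale (~13,000 expressed genes) runs the same way, just slower.

Pattern classes are assigned deterministically (first floor(f*G) genes per
class after a seeded shuffle) so truth fractions are exact. Planted genes
are placed at 300–900 TPM baselines: recovery is meant to measure the
classifier, not sequencing depth. Defaults plant 2.5% over-dominance, 2.5%
under-dominance, 2.5% maternal-ELD and 12% additive genes; the large
additive class keeps the mid-parent BH family mostly null, countering the
plug-in null's inflation so that planted-additive recovery sits near
1 - 2*alpha. The two maternal lines' planted levels are separated by
rho = 0.7 (BC side relative to AC side) so the trio ordering is
deterministic in expectation; the consequence is that the BC-side
dominance/ELD fold is `effect_size * rho` = 2.8 rather than 4. Additive
genes split the parents asymmetrically (up: maternal at 4x the paternal;
down: maternal at 1/16, BB at 1/3) because the mid-parent value compresses
hybrid-vs-CC folds toward 1 on the down side; the chosen split keeps the
weakest contrast (BC at 2/3 of CC) detectable at the planted depths.
Background genes are null — hybrids exactly at their own mid-parent —
with 18% of them drawing independently perturbed maternal levels (2^N(0,1)
fold factors), echoing the observed maternal transcriptome divergence.

What the generator does *not* emulate: the long low-expression tail of real
libraries (planted genes are well-expressed by design; background genes
follow the log-normal), tag-to-gene mapping ambiguity, sequencing error,
and any replicate-level biological variance. Passing recovery tests
therefore demonstrate the pipeline's correctness under its own sampling
model, not robustness to those real-data features.

Annotations: background terms annotate uniform random subsets (10–60
genes); one designated term annotates 80% of a chosen pattern class plus
2% of other genes, giving downstream enrichment a known signal.

## Numerical choices and degenerate inputs

* Half-up decimal rounding via exact `Decimal` division (no float round).
* p-values compared with strict `<` at thresholds; the boundary has
  measure ~0 in practice.
* `alpha = 0` is accepted in pairwise tests and rejects nothing.
* A library with zero total, duplicate gene ids, ragged or non-integer
  rows, and study genes outside the background all raise errors naming the
  offending item; empty annotation files and empty study sets warn and
  return empty results.
* Everything downstream of the generator is deterministic: identical
  inputs and configuration produce byte-identical output tables.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 2,000
genes x 10^6 tags (seconds per fit), oracle enumerations at n ≤ ~2·10^6
with narrow supports, and hypergeometric enumeration at N ≤ 60. These
sizes make every check exact or tightly bounded while keeping runs fast.
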