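# Methods

## The scientific question

In XX individuals one X chromosome is epigenetically silenced (X
chromosome inactivation, XCI), but silencing is incomplete: some genes
"escape" and are expressed from the inactive X (X_i). In rare females whose
XCI is fully skewed toward one parental X (non-mosaic XCI, nmXCI), the
allelic ratio at heterozygous sites directly measures X_i expression. This
package quantifies (i) how the magnitude of escape varies across genes,
tissues and topologically associating domains (TADs), and (ii) how that
magnitude couples to the magnitude of sex-biased expression, separately for
pseudoautosomal (PAR) and non-PAR X-linked (NPX) genes.

## Measures and classification rules

Allelic expression at a gene is

    AE = |0.5 - ref_reads / total_reads|,

0 for balanced biallelic expression, 0.5 for monoallelic expression. All
analyses use the complementary escape scale `1 - AE` in [0.5, 1]. The
classification cutoffs, all strict inequalities and all configurable
(`xciscape.config.Thresholds`):

| quantity | rule | default |
|---|---|---|
| escape call (per observation) | 1-AE >= t | t = 0.6 |
| silenced call | 0.5 <= 1-AE < t | — |
| variable (per gene x tissue) | any disagreement between individuals | — |
| sex bias | male: LFSR < a and beta > 0; female: LFSR < a and beta < 0 | a = 0.05 |
| nmXCI individual | median AE over informative genes > s | s = 0.475 |
| sex-biased regulatory element | p_adj < q, sign of the effect | q = 0.2 |

The escape call at 1-AE >= 0.6 is algebraically identical to the biallelic
rule AE <= 0.4 used by the allelic-expression source data; the acceptance
suite asserts this over a dense grid.

Single-cell allelic measures arriving as X_i/total, X_a/total or X_i/X_a
are harmonized onto X_i/total (`harmonize_xi_fraction`): identity, 1 - x,
and r/(1+r) respectively. Ratios already adjusted for skewing are accepted
as-is; no re-adjustment is attempted.

Genomic intervals are 0-based half-open internally. BED input is read
as-is; gene annotation defaults to 1-based inclusive (biomaRt convention)
and is shifted on read. PAR boundaries are configuration, not code, with
hg38 chrX defaults.

## TAD analyses

For every unordered pair of distinct genes the distance is
`|AE_a - AE_b|`. Pairs are within-TAD when both genes map to the same TAD,
where a gene maps to the TAD containing its interval midpoint (genes in
inter-TAD gaps are excluded; if overlapping TADs both contain a midpoint
the smaller start wins, with a warning). The midpoint rule is this
package's choice among defensible assignment rules (any-overlap, TSS).

The permutation test statistic is `median(within) - median(between)`. The
null is built by shuffling the multiset of gene->TAD labels across genes
(TAD sizes preserved) and recomputing pair relations each iteration. The
default alternative is one-sided ("genes within a TAD are more similar"),
p = fraction of null statistics <= observed. The raw fraction is the
default — it can legitimately report p = 0 — and the (b+1)/(n_perm+1)
estimator is available via `corrected=True`.

Two units of analysis are supported (`pair_unit`): `gene_mean` averages AE
per gene across tissues and individuals before forming pairs; `gene_tissue`
forms pairs within each tissue and pools them. Both are defensible readings
of a pooled "all gene x tissue combinations" analysis; the unit used is
recorded in outputs.

Chromosome-scale structure is summarized two further ways: between-TAD
pairs split into adjacent (rank gap 1) vs non-adjacent, compared by a
two-sided Wilcoxon rank-sum test (midranks, exact for small samples via
scipy's method selection); and a Spearman correlation of pair distance on
TAD rank gap.

`tad_anova` decomposes 1-AE variance by sequential (type-I) sums of squares
in the fixed factor order TAD, gene, tissue, computed by incremental
least-squares fits with rank tracking. Because gene is usually nested
within TAD the design is rank-deficient; aliased degrees of freedom are
reported rather than raised. Tukey HSD on TAD means uses the studentized
range. The decomposition identity (factor SS + residual SS = total SS) is
property-tested.

## Escape-bias coupling

Individual-level AE observations are joined to gene x tissue sex effects
(beta_mash with its local false sign rate), so a gene x tissue pair with
several informative individuals contributes several points (a switch
collapses to one row per gene x tissue). Four quadrants are analyzed:
(PAR, male-biased) and (NPX, female-biased), each split at the escape
threshold. Within a quadrant the coupling is the Spearman correlation of
1-AE against beta_mash. Expected signs on the escape side are negative in
both regions: deeper silencing of PAR genes in females leaves relatively
more male expression (beta more positive at lower 1-AE), and fuller NPX
escape adds female expression (beta more negative at higher 1-AE).

Spearman p-values use the asymptotic t approximation for n >= 10 and exact
permutation enumeration below that; per-gene and per-tissue strata with
fewer than 4 complete pairs (configurable) or a constant variable are
skipped with a logged reason.

The tissue-rank analysis computes, per tissue, the median beta and median
1-AE over qualifying observations, then the Spearman correlation across
tissues — the literal computation, on the signed beta scale. Note that on
the signed scale "more escape, stronger female bias" appears as a
*negative* correlation; presentations that rank tissues by bias strength
flip the sign for female-biased sets.

Enhancer proximity: regulatory elements filtered to p_adj < 0.2 and the
requested effect sign define a "near" gene set via their nearest-gene
annotation; a 2x2 Fisher test over a gene universe crosses set membership
with nearness. The universe is a required argument; the package's pipeline
uses all genes of the relevant region class present in the status table.
Zero-cell tables report a conditional-MLE odds ratio of 0 or infinity
(flagged) rather than erroring.

## Categorical tests

`binomial_greater` is the exact one-sided tail P(X >= k | n, p0) with
p0 = 0.5 by default (the convention of the R function this mirrors; the
null probability is configurable). `fisher_2x2` returns the two-sided
hypergeometric p with the conditional-MLE odds ratio. `welch_t` is the
unequal-variance t with Welch–Satterthwaite degrees of freedom. All three
are checked against independent brute-force oracles (pmf tail summation,
full enumeration over fixed margins, hand-computed formula).

## Synthetic data

The generator (`synthetic_data.generate`) emulates the joint structure the
analysis assumes; its defaults are the study conditions, not tuning knobs.
Genes sit inside contiguous 500-kb TADs on a synthetic chromosome with a
PAR1 block first. Escape propensity is logit-additive —
class mean + TAD effect (sd `tad_sd`, default 1.0) + gene effect (sd 0.5) +
gene x tissue jitter (sd 0.3) — mapped to an X_i/total fraction
f = 0.5 * sigmoid(l), so 1-AE_true = 0.5 + f and the escape boundary is
l = logit(0.2). NPX genes are planted 12% consistently escaping and 15%
variable (propensity centred exactly on the call boundary), the fractions
reported for the human X; the rest are silenced (class mean -3). PAR genes
sit high (class mean 1.2), so nearly all PAR observations escape.

Reads are total ~ Poisson(100) with X_i reads beta-binomial
(overdispersion 0.02); the reference haplotype is X_i or X_a with equal
probability per gene x individual. Sex effects couple to the *latent*
escape magnitude for escape-class genes only (PAR:
beta = 0.3 + 4 * AE_true; NPX escape: beta = -0.3 - 4 * (1-AE_true - 0.5);
noise sd 0.05), so the observed-AE correlation is attenuated by read noise
but keeps its sign — which is exactly what the recovery tests check.
Silenced/variable genes draw beta independently of AE, with 11% / 7%
female/male-biased, echoing the reported marginal rates for inactive genes.
The LFSR is a deterministic monotone stand-in,
2 * (1 - Phi(|beta| / beta_noise_sd)) — not a MASH fit (out of scope):
planted biased genes land far below 0.05, null genes get a uniform LFSR
with a realistic ~5% false-sign rate. Mean expression is log-normal and
independent of everything, so expression-correlation analyses have a known
null on synthetic data.

What the generator does **not** emulate: real gene identifiers or hg38
coordinates, sparse tissue coverage (every gene x tissue x individual is
observed), SNP-level aggregation, linkage between expression level and
escape, or MASH's cross-tissue shrinkage correlation. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure, not fidelity to any particular
human dataset.

`toy_fixture()` is a fixed 8-gene / 3-TAD / 2-tissue / 2-individual bundle
whose AE values all derive from small integer read counts; its crosstabs
(PAR: 4 escape-male, 2 silenced-unbiased; NPX: 4 escape-female,
1 escape-unbiased, 1 variable-unbiased, 2 silenced-female,
2 silenced-unbiased) and its single planted variable pair
(NPXG0002 x tissue01) are enumerable by hand and asserted in tests.

## Numerical choices and problem sizes

- Permutation p-values use the raw fraction by default (see above);
  permutation seeds are mandatory and recorded in the result object.
- Ties use midranks throughout (scipy's rankdata / mannwhitneyu / spearmanr
  conventions); exact small-sample paths where noted.
- Calibration and power checks in the test suite run at deliberately small
  scale — 40 genes / 8 TADs for type-I calibration (500 replicates),
  100 genes / 20 TADs for power (200 replicates), 165 genes for
  coupling-sign recovery (200 seeds) — sizes at which the suite completes
  in well under a minute per check while keeping Monte-Carlo error small
  relative to the asserted margins.
- `scripts/acceptance.py` re-runs the default-size study (315 genes,
  40 TADs, 25 tissues, 3 individuals, 1000 permutation iterations) plus a
  200-replicate calibration, and serializes an infinite odds ratio as 1e9
  (JSON has no Infinity).

## Known limitations

- The LFSR stand-in is monotone in |beta| only; it cannot produce the
  sign-uncertain shrinkage patterns of a real multivariate analysis.
- The variable-XCI class is defined by propensity at the call boundary, so
  its realized "variable" rate depends on read depth and tissue jitter.
- The permutation engine shuffles TAD labels at the gene level only; it
  does not model spatial autocorrelation of AE beyond the TAD factor.
- With very few qualifying observations (e.g. the PAR silenced quadrant
  under default conditions) correlation analyses correctly refuse to run
  rather than returning unstable estimates.
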