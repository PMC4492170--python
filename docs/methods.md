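# Methods

## Scope and data model

`methylex` consumes per-cytosine methylation counts (one row per cytosine
residue per strand: chromosome, 1-based position, strand, context,
methylated and unmethylated read counts), gene models in GFF3, repeats in
BED4, per-gene expression in TSV, and GO annotations in long-format TSV.
All internal coordinates are 0-based half-open; files keep their formats'
native conventions. When several mRNA isoforms exist for a gene, the first
one in file order is used, since the analysis attaches a single expression
value per gene.

## Percent methylation

Percent methylation of any cytosine set is **pooled**:
100 · Σ methylated reads / Σ total reads. Pooling weights sites by
coverage, which is robust when per-site depth is low and matches
count-based exports. A per-site mean-of-fractions mode exists behind a
`per_site_mean` flag for sensitivity analysis; the two differ whenever
coverage varies across sites (sites 9/1 and 0/90 pool to 9 % but average
to 45 %). The minimum per-site coverage to include a cytosine defaults to
1 read and is configurable. Strands are counted separately per residue —
CG sites are not collapsed across strands — because the count export is
per-residue. Cytosines whose context is undefined (contig ends, Ns) are
excluded from every summary.

## Context classification

The context of a cytosine is decided by the two bases 3′ of it on its own
strand: CG if the next base is G, else CHG if the base after next is G,
else CHH. On the minus strand the rule is applied to the reverse
complement. The implementation is validated in tests against an exhaustive
scan of all 64 trinucleotides on both strands.

## Gene regions

Each gene defines four strand-oriented intervals: the 1 kb up-stream flank
(5′ of the TSS), the gene body (whole transcribed span, **introns
included**), the first min(500, body length) bp of the body from the TSS,
and the 1 kb down-stream flank anchored at the annotated transcript 3′ end
(a proxy for "downstream of the 3′ UTR", since UTR annotation may be
absent). Flanks are truncated at contig edges and are *not* masked for
overlap with neighboring genes. Genes with a region lacking any covered
cytosine get a missing value there; such genes are dropped listwise from
the model feature table (regression needs complete predictors) but kept in
all other summaries. Genes without expression data are excluded by an
inner join on gene id.

The TSS metaprofile bins [−flank, +flank) in gene orientation (default
100 bp bins, 2 kb flank) and pools counts across genes within a bin; a
per-gene-mean mode is available. Region contrasts (e.g. first 500 bp vs
up-stream) use a two-sided two-proportion z-test on the pooled 2×2 counts;
no particular test is canonical for this comparison, so the choice is
documented here and isolated in one function.

## Expression model

The twelve predictors (nine region × context methylation percentages, exon
length, intron length, exon count) are Z-standardized with the sample SD
(n−1) over the fitted rows; the response is log expression, base 10 by
default (configurable — the base changes coefficients by a constant factor
only). Zero-expression genes are dropped with a logged count.

Candidate terms are all non-constant monomials of total degree ≤ 3:
C(12+3, 3) − 1 = 454. Fits are ordinary least squares with intercept;
"REML" with only fixed effects and an i.i.d. Gaussian residual is
structurally identical to OLS, so no mixed-model machinery is involved.
BIC is computed from the Gaussian log-likelihood at the MLE with parameter
count = terms + intercept + residual variance. Model selection is greedy
forward search: at each step the candidate whose inclusion minimizes BIC
is added (efficiently, by incremental orthogonalization of the candidate
columns against the growing design), stopping when no addition lowers BIC.
Ties within 1e−9 are broken by lower total degree, then lexicographically
smaller exponent vector, making selection fully deterministic. A
bidirectional mode (deletion passes after each addition) is available
behind a flag. Marginality is *not* enforced — a cubic term may enter
without its quadratic — mirroring the reference model, which contains such
sets. Cross-validation partitions genes randomly into k (default 3) folds
differing in size by at most one; each fold is scored as
1 − SSE_holdout/SST_holdout with the held-out mean as baseline.

Numerical notes: rank deficiency is detected by pivoted QR and reported
with the names of the collinear terms; candidates whose orthogonalized
norm falls below 1e−10 of their original norm are frozen out of the
search; the error sum of squares is floored at 1e−300 inside BIC so
perfect fits remain comparable.

## Surface analysis

The packaged reference model carries 28 coefficient estimates (29 factors
with the intercept) with standard errors, t and p values. The predictor
written "Percent CG" in the source tables is mapped to gene-body CG
methylation: its cubic coefficient (−0.0277) matches the simplified text
model's −0.03 cubic and its up-stream-CHH interaction (0.0167) matches the
text's +0.02, and no other predictor is consistent with both.

A conditional profile substitutes fixed Z values into all but one
predictor, reducing the polynomial to an exact univariate cubic
c₀ + c₁x + c₂x² + c₃x³. Stationary points are the real roots of the
derivative classified by the second derivative (roots with numerically
zero curvature — the saddle of a pure cubic — are excluded); the
inflection point is −c₂/(3c₃). Locations are reported at full precision;
where compared against two-decimal published values, a ±0.01 tolerance is
used because those values appear truncated rather than rounded.

The nested simplified models f¹…f⁶ add blocks cumulatively: linear
(2.61 − 0.07 m_cg), quadratic (−0.10 m²), cubic (−0.03 m³), the up-stream
CG interaction (−0.02 u_cg·m), three positive interactions
((0.02 u_chh + 0.02 m_chh + 0.04 l_exon)·m), and the quadratic exon
interaction (+0.03 l_exon·m²) with an optional independent exon-length
effect (0.08 l_exon − 0.02 l_exon²). Interaction values contribute only at
or above their introduction level. One known caveat: the source text's
worked f⁵ maximum (−0.05 at u_chh = m_chh = l_exon = 1, u_cg = 0) is not
reproducible from its own printed coefficients (direct evaluation gives
≈ +0.056); the package implements the printed coefficients faithfully and
does not treat that worked value as a reference. Likewise the relative
"35 % higher expression" claim between m_cg = ∓1 is consistent with
neither base-10 (≈ 38 %) nor natural (≈ 15 %) logs and is not reproduced.

Z ↔ percent conversion is the affine map percent = mean + SD·z, with
anchors recovered from printed (z, percent) pairs: gene-body CG mean 56 %,
SD 24 %; up-stream CG mean 53.05 %, SD 28.95 %.

## Enrichment

The focal set is the genes strictly above the (1 − fraction) quantile of
gene-body CG methylation (default top 10 %); ties at the threshold are
excluded, so a degenerate all-equal measure yields an empty set rather
than an arbitrary subset. Each GO term is tested two-sided with Fisher's
exact test; Benjamini–Hochberg adjusted p-values are reported alongside
raw ones (the uncorrected behavior remains reproducible from the raw
column). Unannotated genes stay in the universe and inform the
"without-term" cells.

## Synthetic data generator

The generator emulates the *statistical* structure the analysis consumes,
not sequence-level biology. Per gene, a 9-dimensional latent Gaussian
vector with a fixed correlation matrix (Gaussian copula) is mapped through
probit-normal marginals to region × context methylation propensities; the
offset of each marginal is chosen so the cohort mean hits its target
exactly. Default targets (methylated proportions): gene body
0.56/0.038/0.012 (CG/CHG/CHH), first 500 bp 0.28/0.032/0.019, up-stream
0.35/0.11/0.027, intergenic 0.75/0.45/0.072, TEs 0.73/0.36/0.063. The
down-stream flank has no published target and reuses the up-stream one (a
convention, recorded here). The default correlation matrix encodes strong
within-region CHG–CHH coupling (0.7), weak body-CG/up-stream-CG coupling
(0.14) and slightly negative flank-CHH/body-CG couplings; it is positive
semi-definite with smallest eigenvalue ≈ 0.19. Latent spreads (0.8 for CG
and CHG, 0.7 for CHH) put the gene-level SD of body CG near 25 percentage
points, matching the anchor-implied spread.

Per-cytosine counts are beta-binomial (default ρ = 0.08) around the
enclosing stratum's mean. The rest-of-body mean is solved per gene so that
the whole body pools to the body target even though the first 500 bp has
its own (dipped) target; genes with bodies ≤ 500 bp use the body mean
throughout. Read depth is negative binomial with mean 19 and size 0.36,
which puts the median at 6 (long-tailed coverage); zero-depth sites are
absent from the table, so recorded coverage follows the zero-truncated
distribution (conditional mean ≈ 24.9). The spike-in contig is methylated
only at the conversion-failure rate (default 0.006, i.e. 99.4 %
conversion). Expression is the reference polynomial model evaluated on the
cohort's standardized features plus Gaussian noise; the default residual
SD is 0.64 (the reference fit's RMSE), and `residual_sd=None` calibrates
the noise so the expected R² equals `target_r2` (default 0.201775). With
the default copula the polynomial signal variance is larger than in the
reference data, so the fixed-0.64 default yields an expected R² near 0.31;
the calibrated mode is what reproduces the ~0.20 headline. A configurable
GO term is planted among top-decile body-CG genes at a target odds ratio
(default 4) for power checks of the enrichment stage.

Everything derives from one seed; equal seeds give byte-identical output
files. Genes are placed left-to-right with ≥ 1 kb clearance so flanks stay
intergenic, and repeats are placed in the remaining intergenic space away
from flanks.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence-dependent methylation motifs,
spatial autocorrelation along chromosomes beyond region structure,
chromosome-level methylation/expression differences (chromosome assignment
is round-robin), mapping artifacts, and read-level error. Recovery tests
demonstrate the pipeline's correctness under the assumed model, not the
model's biological fidelity.

## Problem sizes used in the test suite

Cytosine-level checks run on a 200-gene, ~1 Mb two-chromosome bundle
(~330 k cytosine records); regression-recovery and calibration checks use
the gene-level tier at the default 5,000-gene cohort; the stepwise support
recovery check uses n = 2,000 with 12 linear candidates. These sizes give
standard errors small enough for 3-SE recovery bounds while keeping the
whole suite under a minute.

## Known limitations

- The BIC search is greedy; it is deterministic and fast but not
  guaranteed to find the global BIC minimum over all 2^454 subsets.
- Fisher's exact test is conservative under the null (fewer than 5 % of
  null tests fall below p = 0.05).
- The one-way chromosome ANOVA assumes homoscedastic groups.
- Windows and regions assume a single sample; no differential methylation
  between samples is attempted.
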