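# Methods

## The two prediction frameworks

Both frameworks model a gene's (pre-normalized, covariate-corrected)
expression as a linear function of cis genotype dosages — counts of a
designated effect allele, 0/1/2 — from SNPs within 1 Mb of the gene body
(window closed at both ends, anchored on gene start/end rather than the
TSS; the two anchorings differ by at most the gene length and the gene
bodies simulated here are short).

**Clumped polygenic scorer.** Marginal model: each cis SNP is regressed
individually against expression by OLS *with an intercept* and the
two-sided t-test p-value on n−2 df. Although the marginal model is often
written without an intercept, a no-intercept regression on non-centered
expression is not meaningful, and the standard eQTL scan implementations
include one; samples missing the genotype at a SNP are dropped pairwise for
that SNP only, avoiding imputation bias during fitting. SNPs with p below
the nominal threshold (default 0.05) are then clumped: candidates are
visited in ascending p order (ties broken by chromosome, position, SNP id
for determinism) and retained only if their reference-panel r² with every
already-retained SNP stays at or below the threshold (default 0.3). This
keep-best pass is equivalent to the significance-ordered pairwise-exclusion
iteration ("for each high-LD pair drop the less significant member,
rescan"); the test suite guards the equivalence against a literal
implementation of the latter. LD is the squared Pearson correlation of
dosages in the panel (composite genotypic LD — panels may be unphased).

Each retained SNP carries its marginal β and an adjustment factor
β·(P₁ + 2·P₂), where P₁ and P₂ are the empirical fractions of called panel
individuals with dosage 1 and 2. "Proportions" are genotype-class
fractions, not Hardy–Weinberg expectations from allele frequency: the
centering should reflect the panel as observed. The proportions refer to
the *tested/effect* allele — the same allele the β weighs — which is the
only reading that makes the centering exact: with it, each SNP term has
mean exactly zero over the panel (asserted to 1e-12 in the tests), so a
sample missing every model SNP scores exactly 0, the panel-expected score.
SNPs absent from a scoring cohort are treated as missing (contribution 0),
not as errors, because cross-cohort SNP overlap is never complete. SNPs
absent from, or monomorphic in, the panel are dropped from the model
outright — they can be neither clumped nor centered.

**Elastic-net comparator.** All cis SNPs enter one coordinate-descent
elastic net with mixing parameter α = 0.5 (equal L1/L2 blend) and the
penalty weight chosen by internal 10-fold CV minimizing MSE over a
100-point log-spaced path, seeded for reproducibility. Missing dosages are
mean-imputed per SNP for fitting (the solver needs a complete design; the
fitting convention is otherwise unconstrained), but replaced by zero at
scoring time — the historical convention of this model family, which treats
a missing genotype as an effect-allele-free homozygote. That asymmetry
versus the panel-centered treatment above is precisely the methodological
contrast the package exists to study. Dosages are not standardized before
penalization. No model-quality filter is applied at training time;
significance is decided uniformly by the validation protocol for both
frameworks.

## Validation and comparison protocol

*Internal*: seeded uniform 5-fold split, shared by all genes of a run so
whole-run comparisons are over identical partitions. Each fold retrains the
entire pipeline on the other four folds — association scan, clumping and
adjustment (or the penalized fit) never see hold-out expression; the panel
is external by construction. Per fold, Pearson r between score and observed
expression with its exact two-sided p (equivalent to the t transform
r·√((n−2)/(1−r²)) on n−2 df). Degenerate folds (constant score, e.g. a null
model) contribute r = 0, p = 1 and are retained, keeping the Fisher
combination at fixed df = 10 and penalizing empty models rather than
erroring. Fold p-values are combined as −2Σln p against χ²(10), with
p-values clamped to [1e-300, 1] before the logarithm. A model is
significant iff |r_avg| > 0.1 AND Fisher p < 0.05 — exactly the printed
dual criterion, asserted as a conjunction. No multiple-testing correction
across genes is applied, matching the protocol being reproduced.

*External*: the trained model scores an independent cohort with its own
framework's missing-data convention; significance is p < 0.05 on the
Pearson correlation. A constant score vector yields r = 0, p = 1.

*Comparison*: over genes significant in both arms (set intersection,
sorted), the per-gene explained-variance metrics are compared with a
two-tailed paired t-test (sample SD, n−1 denominator). The effect size is
the paired standardized mean difference d_z = |mean(diff)|/sd(diff) =
|t|/√n, reported non-negative. This is the only definition consistent with
all eight published (df, t, d) triplets (e.g. 13.86/√228 = 0.92); a
pooled-SD d does not reproduce them.

## The simulator

Genotypes follow a threshold-Gaussian model: per haplotype, a latent MVN
with block-diagonal equicorrelation (constant ρ within blocks of
`block_size` SNPs, zero between) is thresholded at each SNP's MAF quantile;
two haplotype draws sum to the dosage. This gives direct, analytic control
over the dosage r² structure that the clumping stage consumes — the reason
it was chosen over coalescent simulation. Expression is a sparse causal
model: `n_causal` SNPs per gene with standard-normal effects, plus Gaussian
noise scaled so the genetic variance fraction matches `h2` empirically in
each cohort (at h² = 0 expression is pure noise; at h² = 1 it is exactly
the genetic value). Three cohorts — training, reference panel (no
missingness), external — share one architecture (MAFs, blocks, causal
effects) and disjoint sample namespaces. Everything is bit-reproducible
from one seed.

Defaults mirror the real study design: 150 training samples (the real
training cohorts had 127–158), a 503-individual panel, 214 external
samples, 100 cis SNPs per gene in blocks of 10 with ρ = 0.8, MAF uniform on
[0.05, 0.5] (the real cohorts were MAF-filtered at 5%), one causal SNP,
h² = 0.5, 2% missing genotypes.

What the simulator does *not* emulate: realistic human LD maps and
recombination, population structure and panel/cohort ancestry mismatch
(the real reference panel is a different population; a matched panel
isolates method behavior from panel mismatch — mismatched panels can be
produced by simulating two studies with different seeds), trans effects,
covariates, and expression-platform differences between cohorts. Passing
tests therefore demonstrate internal correctness and qualitative behavior
of the methods, not real-data performance levels; the real-data
significant-model proportions and table t statistics depend on restricted
individual-level data and are not reproducible here. What *is* fully
reproducible — and asserted — is the internal consistency of every printed
(df, t, d, p) row.

Two threshold-model caveats surfaced during calibration and are reflected
in the tests: dosage r² between latent-correlated SNPs attenuates when
their MAFs differ (a MAF-0.09 SNP next to a MAF-0.48 one caps near r² 0.1
even at ρ = 0.95), so LD-calibration checks use comparable MAFs; and at
h² = 0 the dual significance criterion fires at roughly its nominal
chance level (0–3 genes out of 20 across seeds).

## Numerical and degenerate-case choices

- Perfect single-SNP fits give p = 0 (clamped; downstream Fisher clamps at
  1e-300 before logs).
- Monomorphic SNPs and SNPs with fewer than 3 called samples are skipped in
  the scan with a log message; a gene where nothing survives yields a valid
  *null model* (empty weight list) that scores 0 everywhere — genes are
  never silently dropped.
- Clumping ties on p are broken by (chromosome, position, SNP id), making
  output independent of input order.
- Allele harmonization matches loci by (chromosome, position), compares
  allele pairs as sets, flips dosages (2 − d) on opposite orientation, and
  drops mismatches with a warning; dropping strand-ambiguous A/T and C/G
  pairs is available behind a flag, default off. Effect alleles default to
  the VCF ALT allele; every β in a model refers to its stored effect
  allele, so harmonization re-orients cohorts to the model rather than the
  reverse.
- With exact duplicate predictors, the elastic net's ridge component makes
  the duplicated coefficient split cheaper than the single copy, so
  CV-selected fits with and without the duplicate agree only approximately
  (coefficient sums within ~10%, prediction correlation > 0.999) — an
  intrinsic property of the penalty, not an implementation artifact.

## Known limitations

- The cis window is anchored at gene boundaries; TSS-anchored windows are a
  defensible alternative the text being followed does not disambiguate.
- The elastic-net comparator fits on raw dosage scale; whether historical
  weight databases standardized dosages first is undocumented.
- The CLI trains/validates gene-by-gene in a single process; there is no
  parallelism (cohort sizes in scope do not need it).
- Multi-allelic variants are skipped rather than decomposed.
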