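# Methods

## Scope and model

dnvkit analyzes de novo single-nucleotide variants (dnSNVs) in sequenced
parent–child trios. A dnSNV is a Mendelian violation: the proband is
heterozygous at a site where both biological parents are homozygous
reference. At whole-exome depth the dominant failure mode of naive
violation calling is the *missed heterozygote* — a parent who truly carries
the allele but is genotyped homozygous-reference, so the child's inherited
variant masquerades as de novo. The package therefore treats discovery as a
two-stage problem: genotype-level cohort QC, then a candidate cascade whose
decisive step is parental read support.

## Cohort QC

Individual calls failing GQ ≥ 20 or DP ≥ 20 are set missing rather than
dropping the site (GATK genotype-level semantics); a site then fails when
cohort missingness reaches 10% or it falls in a blacklist region (BED,
0-based half-open, converted once at the boundary to the package's 1-based
convention).

Sex is imputed from X heterozygosity: F = 1 − observed/expected
heterozygote counts, expectation under Hardy–Weinberg at cohort allele
frequencies over informative (polymorphic, non-missing) non-PAR X sites.
F > 0.8 calls male, F < 0.2 female; fewer than 50 informative sites or zero
expected heterozygosity yields "undetermined". The 0.2/0.8 thresholds are
the convention of the standard sex-check tooling.

Relatedness uses the KING-robust estimator
φ̂ = (N_het,het − 2·N_opposite-hom) / (N_het(i) + N_het(j)) over shared
non-missing autosomal genotypes (≥ 1000 by default), classified at the
standard 2^−1.5 … 2^−4.5 cutoffs. Trio validation requires both
parent–proband pairs first-degree; the parent pair must show no
second-degree-or-closer relatedness (the non-consanguinity question —
a strict "unrelated" call is not demanded because sampling noise at a few
thousand SNPs can push a truly unrelated couple's φ̂ marginally above the
0.0442 cutoff).

Ancestry PCA standardizes SNP columns by reference mean dosage and
√(2p̂(1−p̂)), takes the SVD of the reference panel only, and projects cohort
samples onto those axes. A sample is an outlier when any of the first five
PCs deviates more than 6 SDs from the target reference cluster's centroid;
the 6-SD centroid rule is this package's choice (the tight-clustering
criterion it operationalizes is usually applied by eye).

## Discovery cascade

Candidates (het proband, homref parents, all calls non-missing) pass
through seven independent predicates, each recorded in an ordered trail:
retained consequence class (missense/nonsense/splice/synonymous, collapsed
from VEP terms with splice_region included in splice); cohort singleton
(counting proband genotypes only — a parental carrier would already fail
the Mendelian step); population allele frequency < 1%, with "absent from
the reference population" passing and kept distinct from 0; proband alt
fraction ≥ 0.30 (boundary kept) and parental alt fraction ≤ 0.05 (boundary
kept), both computed from AD rather than DP since DP may count other
alleles; minimum base quality ≥ Q20; and a Fisher-exact strand-bias test
failing at Phred ≥ 60 (the FS convention). A predicate whose inputs are
unavailable records "not-evaluable" and never fails a candidate. Because
the predicates are independent, the pass set is invariant to evaluation
order; the trail order is presentational. Probands exceeding five passing
calls are flagged (exclusion is a pipeline switch); deleteriousness tiers
use CADD PHRED > 20 (top 1% of possible human SNVs), strictly.

## Burden statistics

The observed mutation rate is
(n_dnSNVs/n_probands)/(exome_size × n_gametogeneses) with the RefSeq hg19
coding exome (33,828,798 bp) and two gametogeneses as defaults. The default
95% CI is the normal approximation on the per-proband count vector
(mean ± 1.96·sd/√n, scaled by the per-proband denominator); an
exact-Poisson alternative (chi-square bounds on the total count) is
provided and labelled. On the bundled 34/36 cohort the normal-counts CI is
(9.35×10⁻⁹, 1.86×10⁻⁸).

The nonsynonymous (missense + nonsense + splice) : synonymous comparison
conditions on the total: under the null the nonsynonymous count is
Binomial(total, ½). The two-sided exact p and Clopper–Pearson CI on the
proportion (mapped to a ratio via q/(1−q)) are reported. For 20:14 the
ratio is 1.43 with p = 0.39.

Expected class counts come from a mutational-model probability table:
per gene and class, the probability of a dnSNV in one gene copy per
generation. The builder enumerates all three alternative alleles at every
CDS position of a toy gene model plus intronic positions within the splice
window (intronic 1–8 and exonic 1–3 from each internal boundary, mirroring
the consequence mapping), classifies each substitution by codon translation
(amino-acid change → missense, gained stop → nonsense, preserved residue or
retained stop → synonymous; loss of a stop codon is grouped with missense)
with splice-window membership taking precedence so classes partition the
substitution space, and sums trinucleotide-context rates. Sites lacking a
full context (gene edges without flanks, ambiguous bases) are skipped and
counted. The rate table is user input (a uniform toy table ships for
tests); the published human tables are external data and out of scope —
the bundled `exome_class_probabilities.tsv` instead carries the aggregate
exome-wide class probabilities implied by the mutational model for the
bundled cohort's analysis. Enrichment per class is
expected = 2 × n_probands × ΣP, p = P(X ≥ observed) under
Poisson(expected), BH-FDR across the tested classes.

## Gene context

Overlap reporting is exact symbol intersection after case-folding — no
alias resolution, deterministically ordered. Set enrichment is the
hypergeometric upper tail (equivalently one-sided Fisher) with BH-FDR per
library; the default universe is the union of the library's genes, a
supplied background is accepted, and consensus across two library runs
reproduces the keep-only-pathways-confirmed-by-both practice. Expression
presence takes a gene × tissue median-TPM matrix and flags TPM ≥ 1
(boundary kept); missing genes report "unmeasured".

## Clinical models and power

Four canonical models run on the per-proband phenotype table with listwise
deletion: OLS of dnSNV count on father (and separately mother) age at
conception; OLS of age at diagnosis on dnSNV count; and logistic
regression of severity (CY-BOCS total ≥ 24, scored probands only) on dnSNV
count, first-degree-relative diagnosis, brain trauma, comorbidity, sex,
age at diagnosis and five ancestry PCs — the severity model follows the
fuller formula whose rows the cohort's published results table reports.
Each model BH-adjusts its predictors' p-values. Diagnostics: Shapiro–Wilk
residual normality and VIFs (flag ≥ 5) for OLS; Wald CIs, McFadden R²
(flag > 0.4), VIFs (flag ≥ 10) and an events-per-variable flag (< 10) for
the logistic model. Rank-deficient designs raise an error naming the
collinear columns; complete separation raises an error naming the
separating predictor.

Post hoc power inverts the noncentral-F power function of the linear-model
F test with numerator df u = number of non-intercept predictors,
denominator df v = n − u − 1 and noncentrality λ = f²(u + v + 1), solved by
bracketed root-finding to |Δpower| < 10⁻⁶. This is the only convention
under which the four cohort models (N = 32, 31, 36, 30 with 7, 7, 7, 11
predictors) give minimal detectable f² of 0.592, 0.618, 0.507 and 0.900 —
all "large" (> 0.35). The central case λ = 0 falls back to the central F
tail because scipy's noncentral F is degenerate there. The alternative
numerator-df choice (a single focal predictor) is available by passing u
directly.

## Synthetic cohort generator

The generator's defaults encode the study design: 36 trios; true dnSNVs
per proband ~ Poisson(1.4×10⁻⁸ × 33,828,798 × 2 transmitting copies)
≈ Poisson(0.947), placed uniformly on a toy gene map (150 genes × 1.5 kb —
desk-scale coordinates, not real genome positions); proband heterozygous
with Binomial(depth, ½) alt reads, parents with zero alt reads. The class
mix (missense .625, nonsense .040, splice .025, synonymous .310) makes the
expected nonsynonymous:synonymous ratio the 2.23:1 genome-wide expectation
for coding de novo SNVs. Inherited sites (2000 by default; 80% common with
MAF ~ U(0.05, 0.5), 20% rarer) follow Hardy–Weinberg parents and Mendelian
transmission and double as the kinship/PCA substrate; 300 non-PAR X sites
(males hemizygous) drive the sex check. Depths are negative-binomial
(mean 100, dispersion 10 — the study's nominal coverage; the true depth/GQ
distributions of the source data are unpublished, so these are stand-ins);
GQ derives deterministically from the binomial genotype-likelihood margin
with a 1% read-error rate. Missed-heterozygote artifacts convert a truly
heterozygous parent (the other parent homref, child het) to an emitted
homref with residual alt fraction ~ U(0.06, 0.25) at rate 0.005 per
eligible parental het — placed just above the 5% parental-support cutoff so
the cascade's rescue mechanism is testable. Clinical covariates are null by
default: parental ages N(30, 5), age at diagnosis N(13.0, 2.48), CY-BOCS
U{8..36}, binary risk flags Bernoulli(0.2), with missingness fractions
4/36, 5/36 and 6/36 for father age, mother age and CY-BOCS so the four
models' complete-case ns (32, 31, 36, 30) match the study design; optional
log-scale effect sizes (paternal age on the DNV mean, dnSNV count on
severity odds) switch on alternative hypotheses. Everything is reproducible
from the seed and the emitted VCF is byte-identical across runs.

What the generator does *not* emulate — read-level alignment artifacts,
sequencing-error base substitution, LD between sites, realistic gene
lengths and GC structure — bounds what passing tests show: they validate
the statistical machinery and the filter logic against the generative
model, not the behaviour of any specific caller on real reads.

A Balding–Nichols reference-panel generator (ancestral frequencies
U(0.1, 0.9), cluster divergence Fst = 0.15 by default) supports the
ancestry-PCA tests, with cohort samples drawn from one cluster and planted
outliers from another.

## Numerical and scale choices

Stochastic suites are sized to run on one CPU in minutes: the
rate-recovery check uses 200 full simulate→detect→estimate replicates with
50 inherited sites and no X sites (neither enters the rate estimator); the
count-distribution check uses 500 trios; type-I-error calibration uses 500
OLS replicates at n = 36; null calibration of the Poisson enrichment uses
2000 draws. Hypothesis-based property tests are derandomized. BH
adjustment is validated for order preservation, monotonicity in the raw
p-values, p_adj ≥ p and reproducibility; step-up adjustment is not an
idempotent map, so no such property is asserted.

## Known limitations

Only biallelic SNVs are analyzed (indels and structural variants are
dropped at parse); liftover between genome builds is carried as annotation
only; symbol matching has no alias table; the severity model at n = 30
with 11 predictors is deliberately over-parameterized to mirror the study
design and is flagged for low events per variable rather than re-specified.
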