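# Methods

This note records the statistical model behind `dosagecomp`, the knobs
that matter, the numerical conventions, and what the synthetic test bed
does and does not establish.

## Study design assumed

The pipeline targets a pooled bulk RNA-seq design: one male and one female
pool per population (default four populations, so eight RNA libraries),
plus a small number of male-only whole-genome DNA samples (default two)
used to cross-check variant evidence. The sex chromosome is partitioned
into a pseudoautosomal region (default [0, 2.5 Mb)), stratum I
([2.5 Mb, 12 Mb)) and stratum II (12 Mb to chromosome end); all boundaries
are configurable because they are approximate in any real system, and the
chromosome length always comes from input. Coordinates are 0-based
half-open everywhere; GFF3 input is converted on read. A gene belongs to
the compartment containing its start coordinate, so genes straddling a
boundary are counted exactly once (in the left compartment) and
per-compartment gene counts always sum to the total.

## Y-status classification

Filtering keeps biallelic SNPs only (any multi-allelic or indel locus is
dropped) and masks individual calls with genotype quality < 20 or a
best-to-second-best Phred likelihood gap ≤ 25 (the gap must *exceed* the
threshold). "PL margin" is defined from the VCF convention that the best
genotype has PL 0: the margin is the second-smallest PL.

A locus is Y-specific when every male call is heterozygous and every
female call homozygous; a missing call anywhere disqualifies the locus.
This strict universal quantification is deliberately conservative: with
four male pools, a single miscalled pool would otherwise create false Y
variants. Females are not required to share the same homozygous allele by
default; a `female_rule="hom_ref"` strictness flag tightens this to
hom-ref females (the Y variant being a male-restricted derived allele).
The DNA samples are male-only, so DNA Y evidence is "heterozygous in all
DNA males" with the female clause vacuous.

Classification per gene: any in-gene RNA Y site → `transcribed_Y`; no
RNA and no DNA sites → `hemizygous`; exonic DNA sites without RNA →
`silenced_Y`; otherwise (intron-only DNA sites) → `ambiguous`. No minimum
DNA coverage is demanded for a hemizygous call; an optional
minimum-informative-site threshold exists but is off by default. PAR genes
are classified like any others but are never part of the X-linked dosage
sets — the PAR is diploid in both sexes, so "X-linked" has no meaning
there.

Raising either quality threshold can only shrink the Y-specific locus set
(anti-monotonicity), and filtering is idempotent; both properties are
under test.

## Sex-differential expression

The test is a fully specified two-group negative-binomial Wald test, not a
re-implementation of any particular DE package (replicating a specific
tool's shrinkage estimators is a non-goal; the contract here is the same —
NB test, BH at 0.05 — with desk-scale reproducibility):

* size factors: median-of-ratios against the geometric-mean
  pseudo-reference over genes with no zero count;
* dispersion: per-gene method of moments α̂ = max((s² − m̄)/m̄², 10⁻⁸) on
  normalised counts, where s² is the *within-sex pooled* residual variance
  (df = n − 2) and m̄ the overall normalised mean. Using the pooled
  residual rather than the total variance keeps a genuine sex effect from
  inflating the dispersion and destroying power; under the null the two
  coincide in expectation;
* log2 fold change male/female with pseudocount 0.5 on each group mean,
  standard error by the delta method from Var(X) = m + αm²;
* two-sided normal p values, Benjamini–Hochberg across all tested genes
  (all-zero genes are excluded before testing and before BH, which fixes
  the BH family size m at the number of genes actually tested);
* a gene is sex-biased iff adjusted p < α (default 0.05), with the bias
  direction from the fold-change sign.

With four samples per sex the moment dispersion estimate is noisy; raw p
values are mildly anti-conservative in the extreme tail, but the
BH-adjusted false-positive fraction on a 2,000-gene null simulation stays
around 1% (verified in the test suite). Populations are treated as
biological replicates per sex; no population covariate is modelled.

FPKM uses the column sum of the count matrix as "mapped reads":
FPKM = count / (exonic kb) / (library millions). Exonic length is the
length of the exon-interval union.

## Dosage ratios and the pooled-bootstrap null

Per sex, a gene's expression value is its mean FPKM across that sex's
samples ("median" across samples is available as an option); genes below
FPKM 1 are removed per sex — this low-expression filter is applied within
each sex rather than jointly, a documented choice since either reading is
defensible. The statistic is median(region values) / median(autosomal
values), with the even-n median as the central-pair mean.

The null distribution pools region and autosomal values and redraws
n_region and n_autosome values independently with replacement per
replicate (default B = 10,000), recording the ratio of medians. The
equitailed percentile interval at 95% brackets 1 by construction under
exchangeability; an observed ratio outside it is significant. An
alternative stratified mode (each set resampled from itself, interval
around the observed ratio) is available behind `method="stratified"`.
The empirical two-sided p value is twice the smaller tail fraction of
null ratios at or beyond the observed value, each tail with the
(k+1)/(B+1) continuity correction; ties count in both tails, so a fully
degenerate pool yields p = 1 rather than 0. Graded significance codes
(*, **, ***) derive from this p at 0.05/0.01/0.001.

The full analysis computes, per sex: the whole sex chromosome, PAR,
stratum I and stratum II against autosomes (all genes), plus stratum I
and II restricted to X-linked genes — 12 contrasts. The X-linked
*candidate set* is identical for both sexes, so the female X-linked
ratios probe whether male compensation spills over into females; the
per-sex FPKM filter may still drop different low-expression genes per
sex.

Correctness of the bootstrap machinery is established two ways: exact
enumeration on a 3-vs-3 toy (a six-value pool has 6³ × 6³ equally likely
resample pairs, so CI and p are computable in closed form and the
Monte-Carlo run must agree within 3 MC standard errors), and a
calibration simulation (500 exchangeable-null replications, 200 vs 1,000
log-normal values, B = 1,000) whose rejection rate must sit within
5% ± 2 points. These problem sizes were chosen once, as a balance of
Monte-Carlo resolution against desk-scale runtime.

## Synthetic data generator

The generator emulates the design above with known truth. Per gene, a
per-copy rate b ~ LogNormal(μ = 4, σ = 1); expected counts are
rate × exonic kb × library factor, with library factors log-normal at 20%
CV so size-factor estimation is non-trivial, and Gamma-Poisson counts at a
common dispersion (default 0.05). Each pooled library is a single NB draw;
pooling variance is absorbed into the dispersion (no dispersion estimates
exist for the emulated design, so the default favours testability over
realism). Sex rates:

* autosomes: both sexes 2b;
* PAR: diploid in both sexes (male 2b, female 2bh with h = 1 by default);
* strata: female 2bh; male 2b if the Y copy is transcribed, otherwise cb
  with the stratum's compensation factor c ∈ (0, 2].

Ambiguous-status genes (Y present per intronic DNA evidence, expression
status unknown) are given the silenced-type male rate cb. A configurable
fraction of genes receives a sex effect multiplying one sex's rate by
2^effect. The default degeneration mix per stratum mirrors the emulated
system: stratum I mostly retains Y copies (≈30% transcribed, ≈55%
silenced), stratum II is largely deleted (≈68% hemizygous), and roughly
one PAR gene in two hundred carries a Y-specific variant. Default
compensation factors are c = 1.06 (stratum I) and c = 1.58 (stratum II),
i.e. male X-linked:autosome ratios of 0.53 and 0.79, with female factors
0.9 and 1.2; `null_config()` switches every stratum to c = 2, h = 1 and
no sex-biased genes, the exchangeable no-effect configuration.

Genotype patterns satisfy the classification rules by construction.
Good-quality calls are drawn clipped above the default thresholds
(GQ ∈ [21, 99], PL margin ∈ [26, 255]), and a configurable
`low_quality_fraction` of calls (default 2%) falls below them instead —
quality noise is therefore controlled by exactly one knob, and setting it
to 0 makes classification deterministic. Silenced and ambiguous genes
always receive at least one informative site; transcribed-Y genes draw a
Poisson number that may be zero, the one permitted leakage (such genes
classify as hemizygous, and the truth table records the site counts so
tests can condition on informativeness). Background polymorphic sites are
rejected/edited so they can never look Y-specific; a small rate of
multi-allelic and indel junk loci exercises the filters.

Everything is driven by one `numpy` Generator seeded from the config, so
datasets are bit-reproducible and written fixtures byte-identical.

## Parameter recovery and what it shows

The headline validation recovers the stratum II compensation and female
hyperexpression: with the default gene counts (628 stratum II genes,
2,000 autosomal genes) the pipeline's X-linked ratios must land within
±0.05 of the generative oracle — the same ratio-of-medians computed on
the true per-gene rates over the exact gene sets the pipeline selected.
Comparing against the oracle rather than the closed-form c/2 is
deliberate: the ratio-of-medians estimator has ≈0.05 sampling SD around
c/2 at ~500 region genes from a σ = 1 log-normal rate distribution (the
real study's interval half-widths of ≈0.1 at similar sizes show the same
order), so the closed-form value is only recovered to within that
gene-sampling noise, while the oracle comparison isolates what the
pipeline itself adds (counting noise, normalisation, classification),
which is ≈0.01.

Limits of the synthetic evidence: the generator has no mapping bias, no
X/Y read cross-mapping, no population structure between the four
replicate populations, no gene-length–expression correlation beyond the
modelled rate × length mean, and pool-level (not individual-level)
variation. Passing recovery tests therefore validates the inference
machinery, not robustness to those real-data artefacts. The real study's
printed expression ratios depend on unreleased sequencing data and are
not reproduction targets; the in-paper arithmetic (gene densities,
gene-count bookkeeping) is reproduced exactly from printed inputs.

## Degenerate inputs and tie-breaking

Out-of-range positions, non-tiling region maps, empty value sets, zero
autosomal medians, samples with zero total counts, a sex with fewer than
two samples, and datasets without a single all-nonzero gene all raise
typed errors rather than producing numbers. Half-up decimal rounding is
used for printed densities and proportions (so 0.75 → 0.8, matching how
such tables are typeset, rather than banker's rounding). Bootstrap CI
endpoints use `numpy`'s default linear quantile interpolation.
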