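# dosagecomp

Strata-resolved analysis of evolving dosage compensation on young XY sex
chromosomes, with a fully synthetic test bed.

When Y-linked gene copies degenerate, males are left with a single X dose
against the diploid autosomal background. Whether and where regulatory
upregulation compensates for this loss can be read out of bulk RNA-seq:
compare expression of sex-chromosome genes against autosomal genes,
separately per sex and per chromosome region (pseudoautosomal region and
evolutionary strata of increasing Y degeneration), after first working out
— from variant calls alone, without a Y assembly — which genes still have
an expressed Y copy. `dosagecomp` implements that whole inference chain for
study designs like the threespine stickleback system (a PAR covering
roughly the first 2.5 Mb of the sex chromosome, stratum I to 12 Mb,
stratum II beyond), and pairs it with a generative simulator so every step
can be validated by parameter recovery. It is intended for researchers in
sex-chromosome evolution and for method validation at desk scale.

## What it computes

**Y-status classification.** A site that is heterozygous in *every* male
but homozygous in *every* female is a fixed Y variant mapped onto the X
reference. After quality filtering (biallelic SNPs only; a call needs
genotype quality ≥ 20 and a Phred likelihood gap > 25 between best and
second-best genotype), each sex-chromosome gene is typed:

| status | evidence |
|---|---|
| `transcribed_Y` | ≥ 1 Y-specific site in RNA |
| `hemizygous` | no Y-specific sites in RNA or DNA (Y copy lost) |
| `silenced_Y` | exonic DNA Y-specific sites, none in RNA |
| `ambiguous` | remaining patterns (e.g. DNA intron-only sites) |

`hemizygous + silenced_Y` genes are **X-linked**: male expression is
single-X, so their ratio against autosomes measures X<sub>male</sub>:AA
directly.

**Sex contrast.** Per gene, a two-group negative-binomial Wald test of
male vs. female counts: median-of-ratios size factors s_j, per-gene
method-of-moments dispersion α̂ = max((s² − m̄)/m̄², 10⁻⁸) from the
within-sex residual variance, log2 fold change log2((m̄_M + ½)/(m̄_F + ½))
with a delta-method standard error from Var(X) = m + αm², and
Benjamini–Hochberg correction at α = 0.05.

**Dosage ratios.** Per sex and region R, the statistic is
`median(FPKM_R) / median(FPKM_autosomes)` over genes with mean FPKM ≥ 1.
Significance against parity comes from a pooled-bootstrap null: pool both
gene sets, redraw n_R and n_A values with replacement 10,000 times, and
take the equitailed 95% percentile interval of the resampled ratios; an
observed ratio outside the interval rejects "no region effect".

**Simulator.** Per-copy expression rates b are log-normal; females express
2bh (h = stratum hyperexpression factor), males express 2b when the Y copy
is transcribed and cb otherwise, where c ∈ (0, 2] is the compensation
factor (c = 2 restores autosomal output). Counts are Gamma-Poisson with
per-library depth factors; genotype tables are built to satisfy the
classification rules exactly, with controllable quality noise.

## Worked example

```bash
python examples/04_dosage_ratios.py
```

simulates the default design (178 / 658 / 628 genes in PAR / stratum I /
stratum II over 2,000 autosomal genes; stratum I compensation c = 1.06,
stratum II c = 1.58 with female factor h = 1.2) and prints, among the 12
contrasts:

```
    region sex gene_set  observed  ci_lower  ci_upper     p stars
 stratum_I   M X_linked     0.554     0.855     1.155 0.000   ***
stratum_II   M X_linked     0.844     0.876     1.120 0.015     *
stratum_II   F X_linked     1.249     0.887     1.133 0.001   ***
```

The male X-linked ratios recover the configured c/2 (0.53 and 0.79): the
single male X in stratum II is systematically upregulated relative to
stratum I but still short of parity. The female X-linked ratio in
stratum II sits significantly above 1 — the hyperexpression (h = 1.2) that
an unshielded male upregulation drags along in females. Other entry
points: `examples/01…05`, or the CLI (`dosagecomp simulate | classify |
de | dosage | run-all | report`).

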