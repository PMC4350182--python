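"""Synthetic datasets emulating a pooled two-sex, four-population RNA-seq
study of a young XY sex chromosome, with ground truth.

The generator produces a gene annotation across several autosomes and one
sex chromosome partitioned into PAR / stratum I / stratum II, a
negative-binomial count matrix for 2 x n_populations RNA pools, RNA and
DNA genotype tables carrying Y-specific variant patterns, and a truth
table, so the entire inference chain (Y-status classification, sex
contrast, dosage ratios) can be verified by parameter recovery.

Generative expression model, in per-copy rate units ``b`` drawn log-normal
per gene:

* autosomal and PAR genes are diploid in both sexes: mean rate ``2b``
  (PAR females additionally scaled by the PAR female factor ``h``).
* sex-chromosome stratum genes: females carry two X copies, mean
  ``2bh``; males with a transcribed Y copy express both copies, ``2b``;
  males whose Y copy is lost or silent express a single X copy whose
  output is ``cb`` with compensation factor ``c`` in (0, 2] (``c = 1``:
  no upregulation, ``c = 2``: full compensation to autosomal output).
* a configured fraction of genes is sex-biased: one sex's rate is
  multiplied by ``2**effect``.

Expected read counts scale the rate by exonic length (kb) and a
log-normal per-library depth factor; counts are Gamma-Poisson draws with
a common dispersion.  Each pool of individuals is modelled as a single NB
draw, pooling variance being absorbed into the dispersion.

Genotype patterns are generated to satisfy the Y-status rules by
construction: transcribed-Y genes carry exonic sites heterozygous in all
males and hom-ref in all females in both RNA and DNA; silenced-Y genes
carry such sites in DNA exons only; ambiguous genes in DNA introns only;
hemizygous genes carry none.  Background polymorphic sites and junk loci
(multi-allelic / indel) are added to exercise the filters.  Transcribed-Y
genes may draw zero informative sites (the one permitted classification
leakage); silenced and ambiguous genes always receive at least one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .regions import GeneModel, RegionMap, assign_gene_compartment
from .y_status import GenotypeTable, HET, HOM_ALT, HOM_REF

_STATUSES = ("transcribed_Y", "hemizygous", "silenced_Y", "ambiguous")
_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StratumProfile:
    """Y-degeneration mix and expression modifiers for one compartment."""

    frac_transcribed_Y: float
    frac_hemizygous: float
    frac_silenced_Y: float
    frac_ambiguous: float
    compensation: float = 1.0  # c: male single-X output per autosomal copy
    female_factor: float = 1.0  # h: female two-X output multiplier

    def validate(self, name: str) -> None:
        fracs = (
            self.frac_transcribed_Y,
            self.frac_hemizygous,
            self.frac_silenced_Y,
            self.frac_ambiguous,
        )
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-6:
            raise ConfigError(f"{name}: status fractions must be >=0 and sum to 1")
        if not 0 < self.compensation <= 2:
            raise ConfigError(f"{name}: compensation must be in (0, 2]")
        if self.female_factor <= 0:
            raise ConfigError(f"{name}: female_factor must be positive")

    @property
    def probs(self) -> tuple[float, ...]:
        return (
            self.frac_transcribed_Y,
            self.frac_hemizygous,
            self.frac_silenced_Y,
            self.frac_ambiguous,
        )


# Default degeneration mixes follow the study design this emulates:
# stratum I mostly retains (silenced or transcribed) Y copies, stratum II is
# largely deleted from the Y; roughly one PAR gene in two hundred shows a
# Y-specific variant.
DEFAULT_PAR = StratumProfile(0.006, 0.994, 0.0, 0.0, compensation=2.0)
DEFAULT_STRATUM_I = StratumProfile(0.295, 0.027, 0.549, 0.129,
                                   compensation=1.06, female_factor=0.9)
DEFAULT_STRATUM_II = StratumProfile(0.060, 0.680, 0.094, 0.166,
                                    compensation=1.58, female_factor=1.2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for :func:`simulate_dataset`.

    Defaults mirror the emulated design at desk scale: four populations
    of pooled male/female RNA samples, two male DNA samples, 178 / 658 /
    628 genes in PAR / stratum I / stratum II, and a reduced autosomal
    background of 2,000 genes.
    """

    n_autosomal_genes: int = 2000
    n_par_genes: int = 178
    n_stratum_i_genes: int = 658
    n_stratum_ii_genes: int = 628
    # per-copy baseline expression rate: log-normal (natural-log scale)
    log_mean: float = 4.0
    log_sd: float = 1.0
    dispersion: float = 0.05
    n_populations: int = 4
    n_dna_males: int = 2
    frac_sex_biased: float = 0.05
    sex_effect_log2: float = 2.0
    par: StratumProfile = DEFAULT_PAR
    stratum_i: StratumProfile = DEFAULT_STRATUM_I
    stratum_ii: StratumProfile = DEFAULT_STRATUM_II
    # variant sites per gene
    background_snp_mean: float = 2.0
    y_sites_mean: float = 2.0
    junk_site_rate: float = 0.05
    # call-quality model: good calls always clear the default thresholds,
    # a low_quality_fraction of calls falls below them
    gq_mean: float = 60.0
    gq_sd: float = 10.0
    pl_margin_mean: float = 80.0
    pl_margin_sd: float = 15.0
    low_quality_fraction: float = 0.02
    library_size_sigma: float = 0.2
    # geometry
    n_autosomes: int = 4
    autosome_length: int = 20_000_000
    sex_chrom_length: int = 20_000_000
    par_end: int = 2_500_000
    stratum_i_end: int = 12_000_000
    sex_chrom_name: str = "chrXIX"
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_autosomal_genes,
            self.n_par_genes,
            self.n_stratum_i_genes,
            self.n_stratum_ii_genes,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("gene counts must be non-negative")
        if sum(counts) == 0:
            raise ConfigError("no genes configured")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.n_populations < 2:
            raise ConfigError("need at least two populations per sex")
        if not 0 <= self.frac_sex_biased <= 1:
            raise ConfigError("frac_sex_biased must be in [0, 1]")
        if not 0 <= self.low_quality_fraction < 1:
            raise ConfigError("low_quality_fraction must be in [0, 1)")
        self.par.validate("par")
        self.stratum_i.validate("stratum_i")
        self.stratum_ii.validate("stratum_ii")
        if not 0 < self.par_end < self.stratum_i_end < self.sex_chrom_length:
            raise ConfigError("sex chromosome boundaries out of order")


@dataclass
class SimulatedDataset:
    genes: list[GeneModel]
    region_maps: dict[str, RegionMap]
    counts: CountMatrix
    rna_genotypes: GenotypeTable
    dna_genotypes: GenotypeTable
    truth: pd.DataFrame  # indexed by gene id
    library_factors: pd.Series  # per-RNA-sample depth factor
    config: SimulationConfig


def _place_genes(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    prefix: str,
) -> list[GeneModel]:
    """Non-overlapping two-exon genes spread evenly over [lo, hi)."""
    if n == 0:
        return []
    slot = (hi - lo) // n
    if slot < 4000:
        raise ConfigError(
            f"{chrom}: {n} genes do not fit in {hi - lo} bp "
            f"(need >= 4 kb per gene)"
        )
    genes = []
    for i in range(n):
        e1 = int(rng.integers(300, 1200))
        intron = int(rng.integers(200, 1200))
        e2 = int(rng.integers(300, 1200))
        span = e1 + intron + e2
        base = lo + i * slot
        start = base + int(rng.integers(0, min(slot - span, slot // 4)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"{prefix}{i:05d}",
                chromosome=chrom,
                start=start,
                end=start + span,
                strand=strand,
                exons=((start, start + e1), (start + e1 + intron, start + span)),
            )
        )
    return genes


def _unique_positions(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    k: int,
    used: set[int],
) -> list[int]:
    """k distinct unused positions drawn from intervals, length-weighted."""
    lens = np.array([e - s for s, e in intervals], dtype=float)
    out: list[int] = []
    tries = 0
    while len(out) < k and tries < 200 * max(k, 1):
        tries += 1
        i = int(rng.choice(len(intervals), p=lens / lens.sum()))
        s, e = intervals[i]
        pos = int(rng.integers(s, e))
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


class _SiteBuffer:
    """Accumulates variant sites for one genotype table."""

    def __init__(self, sample_ids: list[str]) -> None:
        self.sample_ids = sample_ids
        self.rows: list[tuple[str, int, str, tuple[str, ...]]] = []
        self.genotypes: list[np.ndarray] = []

    def add(
        self,
        chrom: str,
        pos: int,
        ref: str,
        alts: tuple[str, ...],
        gts: np.ndarray,
    ) -> None:
        self.rows.append((chrom, pos, ref, alts))
        self.genotypes.append(gts.astype(np.int8))

    def build(
        self, rng: np.random.Generator, cfg: SimulationConfig, samples: pd.DataFrame
    ) -> GenotypeTable:
        order = sorted(range(len(self.rows)), key=lambda i: self.rows[i][:2])
        sites = pd.DataFrame(
            [self.rows[i] for i in order], columns=["chrom", "pos", "ref", "alts"]
        )
        n_sites, n_samples = len(order), len(self.sample_ids)
        if n_sites:
            g = np.stack([self.genotypes[i] for i in order])
        else:
            g = np.zeros((0, n_samples), dtype=np.int8)
        gq = np.clip(
            rng.normal(cfg.gq_mean, cfg.gq_sd, size=(n_sites, n_samples)), 21, 99
        ).round()
        pl = np.clip(
            rng.normal(cfg.pl_margin_mean, cfg.pl_margin_sd, size=(n_sites, n_samples)),
            26,
            255,
        ).round()
        if cfg.low_quality_fraction > 0 and n_sites:
            low = rng.random((n_sites, n_samples)) < cfg.low_quality_fraction
            gq[low] = rng.integers(0, 20, size=int(low.sum()))
            pl[low] = rng.integers(0, 26, size=int(low.sum()))
        return GenotypeTable(
            sites=sites, genotypes=g, gq=gq, pl_margin=pl, samples=samples
        )


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _background_pattern(
    rng: np.random.Generator, male_cols: np.ndarray, female_cols: np.ndarray, n: int
) -> np.ndarray:
    """A polymorphic pattern that is guaranteed not to look Y-specific."""
    gts = rng.choice(
        [HOM_REF, HET, HOM_ALT], size=n, p=[0.5, 0.3, 0.2]
    ).astype(np.int8)
    males_het = bool((gts[male_cols] == HET).all()) if len(male_cols) else True
    females_hom = (
        bool((gts[female_cols] != HET).all()) if len(female_cols) else True
    )
    if males_het and females_hom and len(male_cols):
        gts[male_cols[0]] = HOM_REF
    return gts


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset; bit-reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ---- annotation and region maps -------------------------------------
    region_maps: dict[str, RegionMap] = {}
    genes: list[GeneModel] = []
    per_autosome = (
        math.ceil(config.n_autosomal_genes / config.n_autosomes)
        if config.n_autosomal_genes
        else 0
    )
    remaining = config.n_autosomal_genes
    for a in range(config.n_autosomes):
        chrom = f"chr{a + 1}"
        region_maps[chrom] = RegionMap.autosome(chrom, config.autosome_length)
        n_here = min(per_autosome, remaining)
        genes += _place_genes(rng, chrom, 0, config.autosome_length, n_here,
                              prefix=f"{chrom}_g")
        remaining -= n_here
    sex_chrom = config.sex_chrom_name
    region_maps[sex_chrom] = RegionMap.sex_chromosome(
        config.sex_chrom_length, sex_chrom, config.par_end, config.stratum_i_end
    )
    genes += _place_genes(rng, sex_chrom, 0, config.par_end,
                          config.n_par_genes, prefix="par_g")
    genes += _place_genes(rng, sex_chrom, config.par_end, config.stratum_i_end,
                          config.n_stratum_i_genes, prefix="strI_g")
    genes += _place_genes(rng, sex_chrom, config.stratum_i_end,
                          config.sex_chrom_length, config.n_stratum_ii_genes,
                          prefix="strII_g")

    gene_ids = [g.gene_id for g in genes]
    compartment = pd.Series(
        {g.gene_id: assign_gene_compartment(region_maps[g.chromosome], g)
         for g in genes},
        name="compartment",
    )

    # ---- ground-truth expression model ----------------------------------
    n_genes = len(genes)
    base = rng.lognormal(config.log_mean, config.log_sd, size=n_genes)
    profiles = {"PAR": config.par, "stratum_I": config.stratum_i,
                "stratum_II": config.stratum_ii}
    status = np.array(["autosomal"] * n_genes, dtype=object)
    comp_factor = np.full(n_genes, np.nan)
    fem_factor = np.ones(n_genes)
    male_rate = 2.0 * base.copy()
    female_rate = 2.0 * base.copy()
    for i, g in enumerate(genes):
        label = compartment[g.gene_id]
        if label == "autosome":
            continue
        prof = profiles[label]
        status[i] = rng.choice(_STATUSES, p=prof.probs)
        fem_factor[i] = prof.female_factor
        female_rate[i] = 2.0 * base[i] * prof.female_factor
        if label == "PAR":
            male_rate[i] = 2.0 * base[i]  # PAR is diploid in males too
        elif status[i] == "transcribed_Y":
            male_rate[i] = 2.0 * base[i]
        else:
            comp_factor[i] = prof.compensation
            male_rate[i] = prof.compensation * base[i]

    sex_effect = np.zeros(n_genes)
    biased = rng.random(n_genes) < config.frac_sex_biased
    signs = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    sex_effect[biased] = (signs * config.sex_effect_log2)[biased]
    male_rate = male_rate * np.where(sex_effect > 0, 2.0**sex_effect, 1.0)
    female_rate = female_rate * np.where(sex_effect < 0, 2.0**-sex_effect, 1.0)

    # ---- RNA counts -------------------------------------------------------
    sample_ids = [f"pop{p + 1}_{sex}" for p in range(config.n_populations)
                  for sex in ("M", "F")]
    sexes = [sid.rsplit("_", 1)[1] for sid in sample_ids]
    rna_samples = pd.DataFrame(
        {
            "sex": sexes,
            "population": [sid.rsplit("_", 1)[0] for sid in sample_ids],
            "assay": "RNA",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    lib = rng.lognormal(0.0, config.library_size_sigma, size=len(sample_ids))
    exlen_kb = np.array([g.exonic_length for g in genes]) / 1e3
    rate = np.where(
        np.array(sexes) == "M", male_rate[:, None], female_rate[:, None]
    )
    mean = rate * exlen_kb[:, None] * lib[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        samples=rna_samples,
    )

    # ---- genotype tables --------------------------------------------------
    dna_ids = [f"dna_M{i + 1}" for i in range(config.n_dna_males)]
    dna_samples = pd.DataFrame(
        {"sex": "M", "population": "NA", "assay": "DNA"},
        index=pd.Index(dna_ids, name="sample_id"),
    )
    rna_buf = _SiteBuffer(sample_ids)
    dna_buf = _SiteBuffer(dna_ids)
    male_cols = np.array([i for i, s in enumerate(sexes) if s == "M"])
    female_cols = np.array([i for i, s in enumerate(sexes) if s == "F"])
    n_rna, n_dna = len(sample_ids), len(dna_ids)
    y_pattern_rna = np.full(n_rna, HOM_REF, dtype=np.int8)
    y_pattern_rna[male_cols] = HET
    y_pattern_dna = np.full(n_dna, HET, dtype=np.int8)
    used: dict[str, set[int]] = {c: set() for c in region_maps}

    n_y_rna = np.zeros(n_genes, dtype=int)
    n_y_dna_ex = np.zeros(n_genes, dtype=int)
    n_y_dna_in = np.zeros(n_genes, dtype=int)
    for i, g in enumerate(genes):
        chrom_used = used[g.chromosome]
        exons = list(g.exons)
        introns = [(g.exons[0][1], g.exons[1][0])]
        on_sex = g.chromosome == sex_chrom
        st = status[i]
        if on_sex and st != "autosomal":
            if st == "transcribed_Y":
                k = int(rng.poisson(config.y_sites_mean))  # zero allowed: leakage
                for pos in _unique_positions(rng, exons, k, chrom_used):
                    ref, alt = _alleles(rng)
                    rna_buf.add(g.chromosome, pos, ref, (alt,), y_pattern_rna)
                    dna_buf.add(g.chromosome, pos, ref, (alt,), y_pattern_dna)
                    n_y_rna[i] += 1
                    n_y_dna_ex[i] += 1
            elif st == "silenced_Y":
                k = 1 + int(rng.poisson(max(config.y_sites_mean - 1, 0)))
                for pos in _unique_positions(rng, exons, k, chrom_used):
                    ref, alt = _alleles(rng)
                    dna_buf.add(g.chromosome, pos, ref, (alt,), y_pattern_dna)
                    n_y_dna_ex[i] += 1
            elif st == "ambiguous":
                k = 1 + int(rng.poisson(max(config.y_sites_mean - 1, 0)))
                for pos in _unique_positions(rng, introns, k, chrom_used):
                    ref, alt = _alleles(rng)
                    dna_buf.add(g.chromosome, pos, ref, (alt,), y_pattern_dna)
                    n_y_dna_in[i] += 1
        # background polymorphisms, not Y-specific by construction
        for pos in _unique_positions(
            rng, exons, int(rng.poisson(config.background_snp_mean)), chrom_used
        ):
            ref, alt = _alleles(rng)
            rna_buf.add(g.chromosome, pos, ref, (alt,),
                        _background_pattern(rng, male_cols, female_cols, n_rna))
            if on_sex:
                dna_gts = rng.choice(
                    [HOM_REF, HET, HOM_ALT], size=n_dna, p=[0.5, 0.3, 0.2]
                ).astype(np.int8)
                if (dna_gts == HET).all():
                    dna_gts[0] = HOM_REF
                dna_buf.add(g.chromosome, pos, ref, (alt,), dna_gts)
        # junk loci exercising the biallelic-SNP filter
        if rng.random() < config.junk_site_rate:
            for pos in _unique_positions(rng, exons, 1, chrom_used):
                ref, alt = _alleles(rng)
                if rng.random() < 0.5:
                    alts: tuple[str, ...] = (alt, str(_BASES[rng.integers(4)]))
                else:
                    alts = (ref + alt,)  # insertion
                rna_buf.add(g.chromosome, pos, ref, alts,
                            _background_pattern(rng, male_cols, female_cols, n_rna))

    rna_table = rna_buf.build(rng, config, rna_samples)
    dna_table = dna_buf.build(rng, config, dna_samples)

    truth = pd.DataFrame(
        {
            "chromosome": [g.chromosome for g in genes],
            "compartment": compartment.loc[gene_ids].to_numpy(),
            "y_status": status,
            "sex_effect_log2": sex_effect,
            "compensation": comp_factor,
            "female_factor": fem_factor,
            "base_rate": base,
            "male_rate": male_rate,
            "female_rate": female_rate,
            "n_y_sites_rna": n_y_rna,
            "n_y_sites_dna_exonic": n_y_dna_ex,
            "n_y_sites_dna_intronic": n_y_dna_in,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedDataset(
        genes=genes,
        region_maps=region_maps,
        counts=count_matrix,
        rna_genotypes=rna_table,
        dna_genotypes=dna_table,
        truth=truth,
        library_factors=pd.Series(lib, index=sample_ids, name="library_factor"),
        config=config,
    )


def null_config(**overrides) -> SimulationConfig:
    """A no-effect configuration: full compensation (c = 2), no female
    hyperexpression, no sex-biased genes."""
    base = SimulationConfig(
        frac_sex_biased=0.0,
        par=replace(DEFAULT_PAR, compensation=2.0, female_factor=1.0),
        stratum_i=replace(DEFAULT_STRATUM_I, compensation=2.0, female_factor=1.0),
        stratum_ii=replace(DEFAULT_STRATUM_II, compensation=2.0, female_factor=1.0),
    )
    return replace(base, **overrides)


def write_fixture(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write a dataset as GFF3 + counts TSV + RNA/DNA VCF + truth TSV.

    Files round-trip losslessly through :mod:`dosagecomp.io` readers and
    are byte-identical for identical datasets.
    """
    from . import io as dio
    from pathlib import Path

    if not dataset.genes:
        raise ValueError("cannot write a fixture with no genes")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": directory / "genes.gff3",
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "rna_vcf": directory / "rna.vcf",
        "dna_vcf": directory / "dna.vcf",
        "truth": directory / "truth.tsv",
        "regions": directory / "regions.yaml",
    }
    dio.write_gff3(dataset.genes, paths["gff3"])
    dataset.counts.counts.to_csv(paths["counts"], sep="\t")
    all_samples = pd.concat(
        [dataset.counts.samples, dataset.dna_genotypes.samples]
    )
    all_samples.to_csv(paths["samples"], sep="\t")
    dio.write_vcf(dataset.rna_genotypes, paths["rna_vcf"], dataset.region_maps)
    dio.write_vcf(dataset.dna_genotypes, paths["dna_vcf"], dataset.region_maps)
    dataset.truth.to_csv(paths["truth"], sep="\t")
    dio.write_region_config(dataset.region_maps, paths["regions"])
    return {k: str(v) for k, v in paths.items()}
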