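"""Y-copy status classification from RNA and DNA genotype evidence.

Without an assembled Y sequence, Y-linked variation shows up in variant
calls against the X reference as sites that are heterozygous in every male
but homozygous in every female: the male-restricted allele is the fixed Y
variant.  Genes are then typed by where such Y-specific sites occur:

* ``transcribed_Y`` — Y-specific sites in the RNA data: the Y copy is
  expressed.
* ``hemizygous`` — no Y-specific sites in RNA or DNA: the Y copy is lost;
  male expression is single-X.
* ``silenced_Y`` — exonic Y-specific sites in DNA but none in RNA: the Y
  copy exists but is not expressed.
* ``ambiguous`` — remaining evidence patterns (e.g. intron-only DNA sites).

``hemizygous`` and ``silenced_Y`` genes together form the "X-linked" set:
male expression originates from the X copy alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GeneModel

# genotype codes in GenotypeTable arrays
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

Y_STATUSES = ("transcribed_Y", "hemizygous", "silenced_Y", "ambiguous")

DEFAULT_GQ_MIN = 20.0
DEFAULT_PL_MARGIN_MIN = 25.0


class GenotypeTableError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Biallelic-SNP genotypes with per-call quality annotations.

    Attributes
    ----------
    sites
        One row per locus: columns ``chrom``, ``pos`` (0-based bp), ``ref``,
        ``alts`` (tuple of alt alleles as read; loci surviving
        :func:`filter_genotypes` have exactly one single-base alt).
    genotypes
        ``(n_sites, n_samples)`` int8 array of {HOM_REF, HET, HOM_ALT,
        MISSING}.
    gq, pl_margin
        Same-shape float arrays: Phred genotype quality, and the Phred gap
        between the second-best and best genotype likelihood (best has
        PL 0 in VCF convention).
    samples
        Indexed by sample id with columns ``sex`` ({M, F}) and ``assay``
        ({RNA, DNA}).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    gq: np.ndarray
    pl_margin: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        n_sites = len(self.sites)
        n_samples = len(self.samples)
        for name in ("genotypes", "gq", "pl_margin"):
            arr = getattr(self, name)
            if arr.shape != (n_sites, n_samples):
                raise GenotypeTableError(
                    f"{name} has shape {arr.shape}, expected {(n_sites, n_samples)}"
                )
        if self.samples.index.has_duplicates:
            raise GenotypeTableError("duplicate sample ids")
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            where = self.sites.loc[dup, ["chrom", "pos"]].iloc[0]
            raise GenotypeTableError(
                f"duplicate locus {where['chrom']}:{where['pos']}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples.index)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise GenotypeTableError(f"unknown sample id(s): {missing}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_rows(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask].copy(),
            gq=self.gq[mask].copy(),
            pl_margin=self.pl_margin[mask].copy(),
            samples=self.samples.copy(),
        )


def _is_clean_biallelic_snp(ref: str, alts: tuple[str, ...]) -> bool:
    if len(alts) != 1:
        return False
    return len(ref) == 1 and len(alts[0]) == 1


def filter_genotypes(
    raw: GenotypeTable,
    gq_min: float = DEFAULT_GQ_MIN,
    pl_margin_min: float = DEFAULT_PL_MARGIN_MIN,
) -> GenotypeTable:
    """Quality-filter a genotype table.

    Loci with more than one alternative allele, or with any indel allele,
    are removed.  At retained loci a sample's call is set to missing when
    its genotype quality is below ``gq_min`` or its PL margin is not
    strictly greater than ``pl_margin_min`` (the likelihood gap has to
    exceed the threshold for the call to be trusted).

    Idempotent: filtering an already filtered table is a no-op.
    """
    keep = np.array(
        [
            _is_clean_biallelic_snp(ref, alts)
            for ref, alts in zip(raw.sites["ref"], raw.sites["alts"])
        ],
        dtype=bool,
    )
    out = raw.subset_rows(keep)
    bad = (out.gq < gq_min) | (out.pl_margin <= pl_margin_min)
    out.genotypes[bad] = MISSING
    return out


def find_y_specific(
    filtered: GenotypeTable,
    male_ids: list[str],
    female_ids: list[str],
    female_rule: str = "any_hom",
) -> set[tuple[str, int]]:
    """Loci heterozygous in all males and homozygous in all females.

    A missing genotype in any named sample disqualifies the locus: the
    universal quantifiers are strict, which is conservative against false
    Y calls.  ``female_rule`` controls the rigor of the female side:
    ``"any_hom"`` (default) accepts any homozygous call, ``"hom_ref"``
    requires all females homozygous for the reference allele (the Y
    variant being a male-restricted derived allele).
    """
    if female_rule not in ("any_hom", "hom_ref"):
        raise ValueError(f"unknown female_rule {female_rule!r}")
    m_idx = filtered.sample_indices(list(male_ids))
    f_idx = filtered.sample_indices(list(female_ids))
    g = filtered.genotypes
    males_ok = (g[:, m_idx] == HET).all(axis=1) if len(m_idx) else np.ones(len(g), bool)
    if len(f_idx):
        gf = g[:, f_idx]
        if female_rule == "hom_ref":
            females_ok = (gf == HOM_REF).all(axis=1)
        else:
            females_ok = ((gf == HOM_REF) | (gf == HOM_ALT)).all(axis=1)
    else:
        females_ok = np.ones(len(g), dtype=bool)
    mask = males_ok & females_ok
    return {
        (c, int(p))
        for c, p in zip(filtered.sites["chrom"][mask], filtered.sites["pos"][mask])
    }


@dataclass(frozen=True)
class YStatusCall:
    """Per-gene Y-copy classification with supporting site counts."""

    gene_id: str
    status: str
    n_rna_sites: int
    n_dna_exonic: int
    n_dna_intronic: int


def classify_gene_y_status(
    gene: GeneModel,
    rna_y_sites: set[tuple[str, int]],
    dna_y_sites: set[tuple[str, int]],
    min_informative_sites: int = 0,
) -> YStatusCall:
    """Type one gene's Y-copy status from Y-specific site locations.

    Any RNA Y-specific site within the gene span means the Y copy is
    transcribed.  Otherwise, no evidence at all means the Y copy is gone
    (hemizygous); exonic DNA evidence without RNA evidence means the Y
    copy exists but is silent; intron-only DNA evidence is ambiguous.

    ``min_informative_sites`` optionally demands at least that many total
    Y-specific sites before a non-hemizygous status is called (off by
    default; no minimum DNA coverage is required for a hemizygous call).
    """
    in_gene = lambda s: s[0] == gene.chromosome and gene.start <= s[1] < gene.end
    rna = [s for s in rna_y_sites if in_gene(s)]
    dna = [s for s in dna_y_sites if in_gene(s)]
    dna_exonic = [s for s in dna if gene.overlaps_exon(s[1])]
    dna_intronic = [s for s in dna if not gene.overlaps_exon(s[1])]

    n_informative = len(rna) + len(dna)
    if n_informative < min_informative_sites:
        rna, dna_exonic, dna_intronic = [], [], []

    if rna:
        status = "transcribed_Y"
    elif not dna_exonic and not dna_intronic:
        status = "hemizygous"
    elif dna_exonic:
        status = "silenced_Y"
    else:
        status = "ambiguous"
    return YStatusCall(
        gene_id=gene.gene_id,
        status=status,
        n_rna_sites=len(rna),
        n_dna_exonic=len(dna_exonic),
        n_dna_intronic=len(dna_intronic),
    )


def classify_genes(
    genes: list[GeneModel],
    rna_y_sites: set[tuple[str, int]],
    dna_y_sites: set[tuple[str, int]],
    min_informative_sites: int = 0,
) -> list[YStatusCall]:
    return [
        classify_gene_y_status(g, rna_y_sites, dna_y_sites, min_informative_sites)
        for g in genes
    ]


def tabulate_y_status(
    calls: list[YStatusCall], compartments: pd.Series
) -> pd.DataFrame:
    """Per-compartment counts of each Y-status class plus a totals row.

    ``compartments`` maps gene id to compartment label.  The X-linked
    column is the hemizygous + silenced_Y total (genes whose male
    expression is single-X).
    """
    ids = [c.gene_id for c in calls]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in Y-status calls")
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "status": [c.status for c in calls],
        }
    )
    df["compartment"] = df["gene_id"].map(compartments)
    if df["compartment"].isna().any():
        missing = df.loc[df["compartment"].isna(), "gene_id"].tolist()
        raise ValueError(f"no compartment for gene(s): {missing[:5]}")
    labels = sorted(df["compartment"].unique())
    rows = []
    for label in labels + ["total"]:
        sub = df if label == "total" else df[df["compartment"] == label]
        counts = sub["status"].value_counts()
        row = {"compartment": label}
        for status in Y_STATUSES:
            row[f"n_{status}"] = int(counts.get(status, 0))
        row["n_X_linked"] = row["n_hemizygous"] + row["n_silenced_Y"]
        rows.append(row)
    return pd.DataFrame(rows)


def x_linked_gene_ids(calls: list[YStatusCall]) -> set[str]:
    """Genes without an expressed Y copy (hemizygous or silenced)."""
    return {c.gene_id for c in calls if c.status in ("hemizygous", "silenced_Y")}
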