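"""Chromosome compartments and gene placement.

The threespine stickleback sex chromosome (XIX) is partitioned into a
pseudoautosomal region (PAR, still recombining in both sexes) and two
evolutionary strata of increasing Y degeneration.  This module represents
such partitions as ordered, exactly tiling interval maps, assigns genes to
compartments, and computes gene densities (genes per Mb).

All coordinates are 0-based half-open.  GFF3 input (1-based inclusive) is
converted on read by :mod:`dosagecomp.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

#: Recognised compartment labels.
COMPARTMENTS = ("PAR", "stratum_I", "stratum_II", "autosome", "unmapped")

#: Default chrXIX boundaries: PAR covers roughly the first 2.5 Mb, stratum I
#: extends from the PAR to 12 Mb, stratum II covers the remainder.
DEFAULT_PAR_END = 2_500_000
DEFAULT_STRATUM_I_END = 12_000_000


class RegionError(ValueError):
    """Invalid region map or out-of-range query."""


@dataclass(frozen=True)
class RegionMap:
    """Ordered compartments tiling one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome name, e.g. ``"chrXIX"``.
    length
        Chromosome length in base pairs.
    compartments
        Ordered ``(label, start, end)`` triples, 0-based half-open, that
        must tile ``[0, length)`` exactly without overlap.
    """

    chromosome: str
    length: int
    compartments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise RegionError(f"chromosome length must be positive, got {self.length}")
        prev_end = 0
        for label, start, end in self.compartments:
            if label not in COMPARTMENTS:
                raise RegionError(f"unknown compartment label {label!r}")
            if start != prev_end:
                raise RegionError(
                    f"compartments must tile the chromosome: expected start "
                    f"{prev_end}, got {start} for {label!r}"
                )
            if end <= start:
                raise RegionError(f"empty compartment {label!r}: [{start}, {end})")
            prev_end = end
        if prev_end != self.length:
            raise RegionError(
                f"compartments end at {prev_end} but chromosome length is {self.length}"
            )

    @classmethod
    def sex_chromosome(
        cls,
        length: int,
        chromosome: str = "chrXIX",
        par_end: int = DEFAULT_PAR_END,
        stratum_i_end: int = DEFAULT_STRATUM_I_END,
    ) -> "RegionMap":
        """Default PAR / stratum I / stratum II partition of chrXIX."""
        return cls(
            chromosome=chromosome,
            length=length,
            compartments=(
                ("PAR", 0, par_end),
                ("stratum_I", par_end, stratum_i_end),
                ("stratum_II", stratum_i_end, length),
            ),
        )

    @classmethod
    def autosome(cls, chromosome: str, length: int) -> "RegionMap":
        """A chromosome that is one single autosomal compartment."""
        return cls(chromosome, length, (("autosome", 0, length),))

    def compartment_lengths(self) -> dict[str, int]:
        return {label: end - start for label, start, end in self.compartments}


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, 0-based half-open coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.end > self.start >= 0:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for es, ee in self.exons:
            if not (self.start <= es < ee <= self.end):
                raise ValueError(
                    f"exon [{es}, {ee}) outside gene span [{self.start}, {self.end}) "
                    f"for {self.gene_id}"
                )
        if self.exonic_length <= 0:
            raise ValueError(f"gene {self.gene_id} has no exonic sequence")

    @property
    def exonic_length(self) -> int:
        """Length of the union of exon intervals in bp."""
        merged_end = -1
        total = 0
        for es, ee in sorted(self.exons):
            if es > merged_end:
                total += ee - es
                merged_end = ee
            elif ee > merged_end:
                total += ee - merged_end
                merged_end = ee
        return total

    def overlaps_exon(self, position: int) -> bool:
        return any(es <= position < ee for es, ee in self.exons)


def compartment_of(region_map: RegionMap, position: int) -> str:
    """Compartment label containing ``position`` (0-based).

    Raises
    ------
    RegionError
        If ``position`` lies outside ``[0, length)``.
    """
    if not 0 <= position < region_map.length:
        raise RegionError(
            f"position {position} outside {region_map.chromosome} "
            f"[0, {region_map.length})"
        )
    for label, start, end in region_map.compartments:
        if start <= position < end:
            return label
    raise AssertionError("unreachable: compartments tile the chromosome")


def assign_gene_compartment(region_map: RegionMap, gene: GeneModel) -> str:
    """Compartment of a gene, determined by its start coordinate.

    Genes straddling a boundary are assigned to the left compartment so
    that every gene is counted exactly once.
    """
    if gene.chromosome != region_map.chromosome:
        raise RegionError(
            f"gene {gene.gene_id} on {gene.chromosome}, region map is for "
            f"{region_map.chromosome}"
        )
    return compartment_of(region_map, gene.start)


def assign_all(
    genes: list[GeneModel], region_maps: dict[str, RegionMap]
) -> pd.Series:
    """Compartment per gene id for genes across several chromosomes."""
    out = {}
    for gene in genes:
        try:
            rmap = region_maps[gene.chromosome]
        except KeyError:
            raise RegionError(f"no region map for chromosome {gene.chromosome!r}")
        out[gene.gene_id] = assign_gene_compartment(rmap, gene)
    return pd.Series(out, name="compartment")


def gene_density(gene_count: int, region_length: int) -> float:
    """Genes per million base pairs, half-up rounded to one decimal."""
    if region_length <= 0:
        raise RegionError(f"region length must be positive, got {region_length}")
    if gene_count < 0:
        raise ValueError(f"gene count must be non-negative, got {gene_count}")
    density = Decimal(gene_count) / (Decimal(region_length) / Decimal(1_000_000))
    return float(density.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compartment_summary(
    genes: list[GeneModel], region_maps: dict[str, RegionMap]
) -> pd.DataFrame:
    """Per-compartment gene counts, lengths and densities.

    Returns a frame with columns ``compartment, n_genes, length_bp, density``
    aggregated over all chromosomes sharing a compartment label.
    """
    assignments = assign_all(genes, region_maps)
    lengths: dict[str, int] = {}
    for rmap in region_maps.values():
        for label, seg_len in rmap.compartment_lengths().items():
            lengths[label] = lengths.get(label, 0) + seg_len
    rows = []
    for label in COMPARTMENTS:
        if label not in lengths:
            continue
        n = int((assignments == label).sum())
        rows.append(
            {
                "compartment": label,
                "n_genes": n,
                "length_bp": lengths[label],
                "density": gene_density(n, lengths[label]),
            }
        )
    return pd.DataFrame(rows)
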