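"""Readers and writers for the standard formats the pipeline consumes.

GFF3 parsing goes through gffutils, VCF parsing through cyvcf2; region
maps travel as a small YAML document; counts, sample sheets and result
tables are TSV with header rows.  GFF3's 1-based inclusive coordinates
are converted to the package's 0-based half-open convention on read.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .expression import CountMatrix
from .regions import GeneModel, RegionMap
from .y_status import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING

_SOURCE = "dosagecomp"


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\t{_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chromosome}\t{_SOURCE}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\t{_SOURCE}\texon\t{es + 1}\t{ee}\t.\t"
                    f"{g.strand}\t.\tID={tid}.e{i};Parent={tid}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    """Load gene models (with exon union per gene) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                exons=tuple(exons),
            )
        )
    return genes


# --------------------------------------------------------------------------
# region config
# --------------------------------------------------------------------------

def write_region_config(region_maps: dict[str, RegionMap], path) -> None:
    doc = {
        "chromosomes": {
            name: {
                "length": rm.length,
                "compartments": [
                    [label, int(s), int(e)] for label, s, e in rm.compartments
                ],
            }
            for name, rm in sorted(region_maps.items())
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_region_config(path) -> dict[str, RegionMap]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for name, entry in doc["chromosomes"].items():
        out[name] = RegionMap(
            chromosome=name,
            length=int(entry["length"]),
            compartments=tuple(
                (label, int(s), int(e)) for label, s, e in entry["compartments"]
            ),
        )
    return out


# --------------------------------------------------------------------------
# counts and sample sheets
# --------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    required = {"sex", "assay"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    return sheet


def read_counts(counts_path, sample_sheet: pd.DataFrame | str | Path) -> CountMatrix:
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    rna = sample_sheet[sample_sheet["assay"] == "RNA"]
    return CountMatrix(counts=counts[list(rna.index)], samples=rna)


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def _pl_triple(gt: int, margin: int) -> str:
    far = margin + 30
    if gt == HOM_REF:
        pls = (0, margin, far)
    elif gt == HET:
        pls = (margin, 0, far)
    elif gt == HOM_ALT:
        pls = (far, margin, 0)
    else:
        pls = (0, 0, 0)
    return ",".join(str(p) for p in pls)


def write_vcf(table: GenotypeTable, path, region_maps: dict[str, RegionMap]) -> None:
    """Write a genotype table as VCF 4.2 with GT/GQ/PL FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={_SOURCE}\n")
        for name, rm in sorted(region_maps.items()):
            fh.write(f"##contig=<ID={name},length={rm.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
        )
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
            '"Phred-scaled genotype likelihoods">\n'
        )
        cols = "\t".join(table.samples.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for i in range(table.n_sites):
            chrom, pos, ref, alts = table.sites.iloc[i][
                ["chrom", "pos", "ref", "alts"]
            ]
            calls = []
            for j in range(len(table.samples)):
                gt = int(table.genotypes[i, j])
                gq = int(table.gq[i, j])
                pl = _pl_triple(gt, int(table.pl_margin[i, j]))
                calls.append(f"{_GT_STRINGS[gt]}:{gq}:{pl}")
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\t.\t.\t"
                f"GT:GQ:PL\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path, sample_sheet: pd.DataFrame) -> GenotypeTable:
    """Load a VCF into a GenotypeTable; metadata comes from the sheet.

    Only GT, GQ and PL FORMAT fields are used.  The PL margin is the gap
    between the second-smallest and smallest Phred likelihood at each
    call; calls with fewer than two valid PL entries get margin 0.
    """
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    missing = [s for s in ids if s not in sample_sheet.index]
    if missing:
        raise ValueError(f"VCF samples not in sample sheet: {missing}")
    samples = sample_sheet.loc[ids]

    rows, gts, gqs, pls = [], [], [], []
    code = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}
    for v in vcf:
        rows.append((v.CHROM, v.POS - 1, v.REF, tuple(v.ALT)))
        gts.append(np.array([code[int(t)] for t in v.gt_types], dtype=np.int8))
        gq = v.format("GQ")
        gqs.append(
            np.full(len(ids), 0.0)
            if gq is None
            else np.where(gq.reshape(-1) < 0, 0.0, gq.reshape(-1)).astype(float)
        )
        pl = v.format("PL")
        if pl is None:
            pls.append(np.zeros(len(ids)))
        else:
            margins = np.zeros(len(ids))
            for j in range(len(ids)):
                vals = np.sort(pl[j][pl[j] >= 0])
                if vals.size >= 2:
                    margins[j] = float(vals[1] - vals[0])
            pls.append(margins)
    n = len(rows)
    return GenotypeTable(
        sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alts"]),
        genotypes=np.stack(gts) if n else np.zeros((0, len(ids)), np.int8),
        gq=np.stack(gqs) if n else np.zeros((0, len(ids))),
        pl_margin=np.stack(pls) if n else np.zeros((0, len(ids))),
        samples=samples,
    )


# --------------------------------------------------------------------------
# fixture round trip
# --------------------------------------------------------------------------

def read_fixture(directory):
    """Load a directory written by :func:`dosagecomp.simulate.write_fixture`.

    Returns ``(genes, region_maps, counts, rna_genotypes, dna_genotypes,
    truth)``; truth is ``None`` when absent (real datasets).
    """
    directory = Path(directory)
    genes = read_gff3(directory / "genes.gff3")
    region_maps = read_region_config(directory / "regions.yaml")
    sheet = read_sample_sheet(directory / "samples.tsv")
    counts = read_counts(directory / "counts.tsv", sheet)
    rna = read_vcf(directory / "rna.vcf", sheet)
    dna = read_vcf(directory / "dna.vcf", sheet)
    truth_path = directory / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", index_col=0) if truth_path.exists() else None
    )
    return genes, region_maps, counts, rna, dna, truth
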