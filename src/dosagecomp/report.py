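"""Pipeline orchestration and summary reporting.

Runs the full chain — (optionally) simulate, classify Y status, test
sex-differential expression, compute FPKM, run the dosage-ratio analysis —
and emits the per-compartment summary table (sex-biased gene counts, gene
densities, transcribed-Y and X-linked tallies) plus a machine-readable run
manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import io as dio
from .dosage import run_dosage_analysis, results_table
from .expression import CountMatrix, fpkm, nb_sex_test
from .regions import GeneModel, RegionMap, assign_all, gene_density
from .simulate import SimulationConfig, simulate_dataset, write_fixture
from .y_status import (
    DEFAULT_GQ_MIN,
    DEFAULT_PL_MARGIN_MIN,
    classify_genes,
    filter_genotypes,
    find_y_specific,
    tabulate_y_status,
    YStatusCall,
)

logger = logging.getLogger("dosagecomp")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths, thresholds and seed governing one pipeline run.

    Either ``input_dir`` (a fixture directory with genes.gff3, counts.tsv,
    samples.tsv, rna.vcf, dna.vcf, regions.yaml) or ``simulate`` must be
    provided.
    """

    out_dir: str | Path
    input_dir: str | Path | None = None
    simulate: SimulationConfig | None = None
    gq_min: float = DEFAULT_GQ_MIN
    pl_margin_min: float = DEFAULT_PL_MARGIN_MIN
    alpha: float = 0.05
    fpkm_min: float = 1.0
    B: int = 10_000
    conf: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise PipelineError(
                "exactly one of input_dir or simulate must be provided"
            )
        if not 0 < self.alpha < 1 or not 0 < self.conf < 1:
            raise PipelineError("alpha and conf must be in (0, 1)")
        if self.B < 1:
            raise PipelineError("B must be >= 1")
        if self.input_dir is not None:
            missing = [
                f
                for f in (
                    "genes.gff3", "counts.tsv", "samples.tsv",
                    "rna.vcf", "dna.vcf", "regions.yaml",
                )
                if not (Path(self.input_dir) / f).exists()
            ]
            if missing:
                raise PipelineError(
                    f"input_dir is missing required file(s): {missing}"
                )


def classify_from_tables(
    genes: list[GeneModel],
    region_maps: dict[str, RegionMap],
    rna_table,
    dna_table,
    gq_min: float = DEFAULT_GQ_MIN,
    pl_margin_min: float = DEFAULT_PL_MARGIN_MIN,
    female_rule: str = "any_hom",
) -> tuple[list[YStatusCall], set, set]:
    """Filter genotypes, find Y-specific sites, classify sex-chromosome genes.

    DNA samples are male-only in this design, so the DNA Y evidence is
    sites heterozygous in every DNA male (the female clause is vacuous).
    Returns (calls, rna_y_sites, dna_y_sites).
    """
    sex_chroms = {
        c for c, rm in region_maps.items()
        if any(lbl not in ("autosome", "unmapped") for lbl, _, _ in rm.compartments)
    }
    rna_f = filter_genotypes(rna_table, gq_min, pl_margin_min)
    dna_f = filter_genotypes(dna_table, gq_min, pl_margin_min)
    rna_males = list(rna_table.samples.index[rna_table.samples["sex"] == "M"])
    rna_females = list(rna_table.samples.index[rna_table.samples["sex"] == "F"])
    dna_males = list(dna_table.samples.index[dna_table.samples["sex"] == "M"])
    rna_y = find_y_specific(rna_f, rna_males, rna_females, female_rule)
    dna_y = find_y_specific(dna_f, dna_males, [], female_rule)
    sex_genes = [g for g in genes if g.chromosome in sex_chroms]
    calls = classify_genes(sex_genes, rna_y, dna_y)
    logger.info(
        "classify: %d RNA Y-specific sites, %d DNA Y-specific sites, "
        "%d sex-chromosome genes classified",
        len(rna_y), len(dna_y), len(calls),
    )
    return calls, rna_y, dna_y


def make_table1(
    genes: list[GeneModel],
    region_maps: dict[str, RegionMap],
    de_results: pd.DataFrame,
    y_calls: list[YStatusCall],
) -> pd.DataFrame:
    """Per-compartment summary of sex-biased genes and Y-copy classes.

    Rows: autosomes, the sex chromosome in total, and each sex-chromosome
    compartment.  Columns: male-/female-biased gene counts, total genes,
    gene density (genes/Mb), transcribed-Y genes, X-linked genes and the
    hemizygous subset.
    """
    comp = assign_all(genes, region_maps)
    bias = de_results["bias"] if "bias" in de_results else pd.Series(dtype=object)
    status = pd.Series(
        {c.gene_id: c.status for c in y_calls}, dtype=object, name="status"
    )
    if status.index.has_duplicates:
        raise ValueError("duplicate gene ids in Y-status calls")

    lengths: dict[str, int] = {}
    for rm in region_maps.values():
        for label, seg in rm.compartment_lengths().items():
            lengths[label] = lengths.get(label, 0) + seg

    sex_labels = [
        lbl for lbl in ("PAR", "stratum_I", "stratum_II") if lbl in lengths
    ]

    def row(name: str, labels: list[str], length_bp: int) -> dict:
        ids = comp.index[comp.isin(labels)]
        b = bias.reindex(ids)
        s = status.reindex(ids)
        return {
            "compartment": name,
            "n_male_biased": int((b == "male").sum()),
            "n_female_biased": int((b == "female").sum()),
            "n_genes": len(ids),
            "gene_density": gene_density(len(ids), length_bp) if length_bp else 0.0,
            "n_transcribed_Y": int((s == "transcribed_Y").sum()),
            "n_X_linked": int(s.isin(["hemizygous", "silenced_Y"]).sum()),
            "n_hemizygous": int((s == "hemizygous").sum()),
        }

    rows = [row("autosomes", ["autosome"], lengths.get("autosome", 0))]
    sex_total_len = sum(lengths[lbl] for lbl in sex_labels)
    rows.append(row("sex_chromosome", sex_labels, sex_total_len))
    for lbl in sex_labels:
        rows.append(row(lbl, [lbl], lengths[lbl]))
    return pd.DataFrame(rows)


def bookkeeping_totals(table: pd.DataFrame) -> dict[str, int]:
    """Summed tallies across the per-location rows of a summary table.

    ``table`` has one row per genomic location (no totals row) with
    columns ``n_male_biased``, ``n_female_biased``, ``n_genes`` and, where
    available, ``n_X_linked``/``n_hemizygous``.  Returns the
    whole-transcriptome totals plus derived closure quantities.
    """
    male = int(table["n_male_biased"].sum())
    female = int(table["n_female_biased"].sum())
    out = {
        "n_male_biased": male,
        "n_female_biased": female,
        "n_de_genes": male + female,
        "n_genes": int(table["n_genes"].sum()),
    }
    if "n_X_linked" in table:
        out["n_X_linked"] = int(table["n_X_linked"].fillna(0).sum())
    if "n_hemizygous" in table:
        out["n_silenced_Y"] = out["n_X_linked"] - int(
            table["n_hemizygous"].fillna(0).sum()
        )
    return out


def proportion(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Half-up rounded share, as printed in summary prose."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages and write result TSVs plus a JSON manifest.

    Returns a mapping of artifact names to paths.  Deterministic for a
    fixed seed.
    """
    config.validate()
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        logger.info("simulate: generating dataset (seed=%d)", config.simulate.seed)
        ds = simulate_dataset(config.simulate)
        write_fixture(ds, out_dir / "inputs")
        genes, region_maps = ds.genes, ds.region_maps
        counts, rna_gt, dna_gt = ds.counts, ds.rna_genotypes, ds.dna_genotypes
    else:
        logger.info("load: reading inputs from %s", config.input_dir)
        genes, region_maps, counts, rna_gt, dna_gt, _ = dio.read_fixture(
            config.input_dir
        )
    logger.info(
        "load: %d genes, %d RNA samples, %d RNA sites, %d DNA sites",
        len(genes), len(counts.counts.columns), rna_gt.n_sites, dna_gt.n_sites,
    )

    calls, _, _ = classify_from_tables(
        genes, region_maps, rna_gt, dna_gt, config.gq_min, config.pl_margin_min
    )
    comp = assign_all(genes, region_maps)
    ystatus = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "status": [c.status for c in calls],
            "n_rna_sites": [c.n_rna_sites for c in calls],
            "n_dna_exonic": [c.n_dna_exonic for c in calls],
            "n_dna_intronic": [c.n_dna_intronic for c in calls],
        }
    ).set_index("gene_id")
    summary = tabulate_y_status(calls, comp)

    de = nb_sex_test(counts, alpha=config.alpha)
    de["compartment"] = comp.reindex(de.index)
    logger.info(
        "de: %d genes tested, %d biased at alpha=%.3g",
        len(de), int((de["bias"] != "none").sum()), config.alpha,
    )

    lengths = pd.Series({g.gene_id: g.exonic_length for g in genes})
    fpkm_mat = fpkm(counts, lengths)

    ratios = run_dosage_analysis(
        fpkm_mat, genes, region_maps, calls, counts.samples,
        B=config.B, conf=config.conf, seed=config.seed, fpkm_min=config.fpkm_min,
    )
    dosage_df = results_table(ratios)
    logger.info("dosage: %d region x sex contrasts", len(dosage_df))

    table1 = make_table1(genes, region_maps, de, calls)

    artifacts = {
        "ystatus": out_dir / "ystatus.tsv",
        "ystatus_summary": out_dir / "ystatus_summary.tsv",
        "de_results": out_dir / "de_results.tsv",
        "fpkm": out_dir / "fpkm.tsv",
        "dosage": out_dir / "dosage.tsv",
        "table1": out_dir / "table1.tsv",
    }
    ystatus.to_csv(artifacts["ystatus"], sep="\t")
    summary.to_csv(artifacts["ystatus_summary"], sep="\t", index=False)
    de.to_csv(artifacts["de_results"], sep="\t")
    fpkm_mat.to_csv(artifacts["fpkm"], sep="\t", float_format="%.6g")
    dosage_df.to_csv(artifacts["dosage"], sep="\t", index=False)
    table1.to_csv(artifacts["table1"], sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "thresholds": {
            "gq_min": config.gq_min,
            "pl_margin_min": config.pl_margin_min,
            "alpha": config.alpha,
            "fpkm_min": config.fpkm_min,
            "B": config.B,
            "conf": config.conf,
        },
        "n_genes": len(genes),
        "n_classified": len(calls),
        "n_de_tested": len(de),
        "n_contrasts": len(dosage_df),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest_path
    logger.info("report: wrote %d artifacts to %s", len(artifacts), out_dir)
    return {k: str(v) for k, v in artifacts.items()}
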