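import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dosagecomp.expression import nb_sex_test
from dosagecomp.report import (
    PipelineConfig,
    PipelineError,
    bookkeeping_totals,
    classify_from_tables,
    make_table1,
    proportion,
    run_pipeline,
)
from dosagecomp.simulate import SimulationConfig, simulate_dataset, write_fixture

SMALL_CFG = SimulationConfig(
    n_autosomal_genes=150,
    n_par_genes=20,
    n_stratum_i_genes=40,
    n_stratum_ii_genes=40,
    low_quality_fraction=0.0,
    frac_sex_biased=0.0,
    seed=17,
)


class TestMakeTable1:
    def test_matches_truth_marginals_on_noiseless_data(self, small_noiseless):
        ds = small_noiseless
        calls, _, _ = classify_from_tables(
            ds.genes, ds.region_maps, ds.rna_genotypes, ds.dna_genotypes
        )
        de = nb_sex_test(ds.counts)
        de["compartment"] = ds.truth["compartment"].reindex(de.index)
        table = make_table1(ds.genes, ds.region_maps, de, calls)
        by = table.set_index("compartment")
        truth = ds.truth
        for label in ("PAR", "stratum_I", "stratum_II"):
            t = truth[truth["compartment"] == label]
            assert by.loc[label, "n_genes"] == len(t)
            # transcribed genes drawn zero informative sites are classified
            # hemizygous (the permitted leakage), so observed transcribed
            # counts never exceed truth
            assert (
                by.loc[label, "n_transcribed_Y"]
                <= (t["y_status"] == "transcribed_Y").sum()
            )
        assert by.loc["autosomes", "n_genes"] == (
            truth["compartment"] == "autosome"
        ).sum()

    def test_bookkeeping_closure(self, small_noiseless):
        """Per compartment: biased + unbiased = total; X-linked =
        hemizygous + silenced."""
        ds = small_noiseless
        calls, _, _ = classify_from_tables(
            ds.genes, ds.region_maps, ds.rna_genotypes, ds.dna_genotypes
        )
        de = nb_sex_test(ds.counts)
        de["compartment"] = ds.truth["compartment"].reindex(de.index)
        table = make_table1(ds.genes, ds.region_maps, de, calls)
        assert (
            table["n_male_biased"] + table["n_female_biased"] <= table["n_genes"]
        ).all()
        status = pd.Series({c.gene_id: c.status for c in calls})
        by = table.set_index("compartment")
        for label in ("PAR", "stratum_I", "stratum_II"):
            ids = ds.truth.index[ds.truth["compartment"] == label]
            s = status.loc[ids]
            assert by.loc[label, "n_X_linked"] == (
                (s == "hemizygous").sum() + (s == "silenced_Y").sum()
            )
            assert by.loc[label, "n_hemizygous"] == (s == "hemizygous").sum()

    def test_empty_de_results_zero_bias_columns(self, small_noiseless):
        ds = small_noiseless
        calls, _, _ = classify_from_tables(
            ds.genes, ds.region_maps, ds.rna_genotypes, ds.dna_genotypes
        )
        table = make_table1(ds.genes, ds.region_maps, pd.DataFrame(), calls)
        assert (table["n_male_biased"] == 0).all()
        assert (table["n_female_biased"] == 0).all()

    def test_totals_helper_and_proportion(self):
        table = pd.DataFrame(
            {
                "n_male_biased": [10, 5],
                "n_female_biased": [2, 8],
                "n_genes": [100, 50],
                "n_X_linked": [0, 30],
                "n_hemizygous": [0, 12],
            }
        )
        totals = bookkeeping_totals(table)
        assert totals["n_de_genes"] == 25
        assert totals["n_genes"] == 150
        assert totals["n_X_linked"] == 30
        assert totals["n_silenced_Y"] == 18
        assert proportion(32, 50) == 0.64
        with pytest.raises(ValueError):
            proportion(1, 0)


class TestRunPipeline:
    def test_end_to_end_and_determinism(self, tmp_path):
        cfg = PipelineConfig(
            out_dir=tmp_path / "run1", simulate=SMALL_CFG, B=300, seed=5
        )
        artifacts = run_pipeline(cfg)
        for name in ("ystatus", "de_results", "fpkm", "dosage", "table1",
                     "manifest"):
            assert Path(artifacts[name]).exists()
        manifest = json.loads(Path(artifacts["manifest"]).read_text())
        assert manifest["n_contrasts"] == 12
        assert manifest["seed"] == 5

        cfg2 = PipelineConfig(
            out_dir=tmp_path / "run2", simulate=SMALL_CFG, B=300, seed=5
        )
        artifacts2 = run_pipeline(cfg2)
        assert (
            Path(artifacts["dosage"]).read_bytes()
            == Path(artifacts2["dosage"]).read_bytes()
        )

    def test_runs_from_fixture_directory(self, tmp_path):
        ds = simulate_dataset(SMALL_CFG)
        write_fixture(ds, tmp_path / "inputs")
        cfg = PipelineConfig(
            out_dir=tmp_path / "out", input_dir=tmp_path / "inputs", B=200, seed=1
        )
        artifacts = run_pipeline(cfg)
        dosage = pd.read_csv(artifacts["dosage"], sep="\t")
        assert len(dosage) == 12

    def test_missing_input_file_named_in_error(self, tmp_path):
        (tmp_path / "inputs").mkdir()
        cfg = PipelineConfig(out_dir=tmp_path / "out", input_dir=tmp_path / "inputs")
        with pytest.raises(PipelineError, match="rna.vcf"):
            run_pipeline(cfg)

    def test_requires_exactly_one_source(self, tmp_path):
        with pytest.raises(PipelineError):
            run_pipeline(PipelineConfig(out_dir=tmp_path))


class TestCli:
    def test_subcommands_on_small_fixture(self, tmp_path):
        from click.testing import CliRunner

        from dosagecomp.cli import main

        ds = simulate_dataset(SMALL_CFG)
        write_fixture(ds, tmp_path / "fix")
        runner = CliRunner()
        fix = tmp_path / "fix"
        res = runner.invoke(
            main,
            [
                "classify",
                "--rna-vcf", str(fix / "rna.vcf"),
                "--dna-vcf", str(fix / "dna.vcf"),
                "--gff", str(fix / "genes.gff3"),
                "--samples", str(fix / "samples.tsv"),
                "--regions", str(fix / "regions.yaml"),
                "--out", str(tmp_path / "ystatus.tsv"),
            ],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            main,
            [
                "de",
                "--counts", str(fix / "counts.tsv"),
                "--samples", str(fix / "samples.tsv"),
                "--out", str(tmp_path / "de.tsv"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert "genes tested" in res.output
        res = runner.invoke(
            main,
            [
                "run-all",
                "--input-dir", str(fix),
                "--out", str(tmp_path / "out"),
                "--B", "200",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "table1.tsv").exists()
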