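import numpy as np
import pandas as pd
import pytest

from dosagecomp.regions import GeneModel
from dosagecomp.y_status import (
    GenotypeTableError,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    classify_gene_y_status,
    filter_genotypes,
    find_y_specific,
    tabulate_y_status,
)
from conftest import make_genotype_table

MALES = [f"pop{i}_M" for i in range(1, 5)]
FEMALES = [f"pop{i}_F" for i in range(1, 5)]

GOOD_GQ = [60.0] * 8
GOOD_PL = [80.0] * 8
Y_PATTERN = [HET, HOM_REF] * 4  # interleaved M, F


def _table(records, rna_samples8):
    return make_genotype_table(records, rna_samples8)


def _interleave(m_vals, f_vals):
    out = []
    for m, f in zip(m_vals, f_vals):
        out += [m, f]
    return out


@pytest.fixture
def samples(rna_samples8):
    # interleaved pop1_M, pop1_F, pop2_M, ... matching Y_PATTERN
    return [(f"pop{p}_{s}", s, "RNA") for p in range(1, 5) for s in ("M", "F")]


class TestFilterGenotypes:
    def test_multiallelic_locus_removed(self, samples):
        t = _table(
            [("chrXIX", 100, "C", ["A", "T"], Y_PATTERN, GOOD_GQ, GOOD_PL)], samples
        )
        assert filter_genotypes(t).n_sites == 0

    def test_indel_locus_removed(self, samples):
        t = _table(
            [
                ("chrXIX", 100, "C", ["CA"], Y_PATTERN, GOOD_GQ, GOOD_PL),
                ("chrXIX", 200, "CT", ["C"], Y_PATTERN, GOOD_GQ, GOOD_PL),
                ("chrXIX", 300, "C", ["T"], Y_PATTERN, GOOD_GQ, GOOD_PL),
            ],
            samples,
        )
        out = filter_genotypes(t)
        assert list(out.sites["pos"]) == [300]

    def test_low_gq_call_set_missing(self, samples):
        gq = [19.0] + [60.0] * 7
        t = _table([("chrXIX", 100, "C", ["T"], Y_PATTERN, gq, GOOD_PL)], samples)
        out = filter_genotypes(t, gq_min=20)
        assert out.genotypes[0, 0] == MISSING
        assert (out.genotypes[0, 1:] != MISSING).all()

    def test_pl_margin_exactly_threshold_is_missing(self, samples):
        """The likelihood gap must exceed the threshold, strictly."""
        pl = [25.0] + [80.0] * 7
        t = _table([("chrXIX", 100, "C", ["T"], Y_PATTERN, GOOD_GQ, pl)], samples)
        out = filter_genotypes(t, pl_margin_min=25)
        assert out.genotypes[0, 0] == MISSING
        pl26 = [26.0] + [80.0] * 7
        t2 = _table([("chrXIX", 100, "C", ["T"], Y_PATTERN, GOOD_GQ, pl26)], samples)
        assert (filter_genotypes(t2, pl_margin_min=25).genotypes[0] != MISSING).all()

    def test_idempotent(self, small_noiseless):
        once = filter_genotypes(small_noiseless.rna_genotypes)
        twice = filter_genotypes(once)
        assert once.sites.equals(twice.sites)
        assert (once.genotypes == twice.genotypes).all()

    def test_duplicate_locus_rejected(self, samples):
        with pytest.raises(GenotypeTableError):
            _table(
                [
                    ("chrXIX", 100, "C", ["T"], Y_PATTERN, GOOD_GQ, GOOD_PL),
                    ("chrXIX", 100, "C", ["G"], Y_PATTERN, GOOD_GQ, GOOD_PL),
                ],
                samples,
            )


class TestFindYSpecific:
    def _one_site(self, samples, pattern):
        return _table(
            [("chrXIX", 100, "C", ["T"], pattern, GOOD_GQ, GOOD_PL)], samples
        )

    def test_all_males_het_all_females_homref(self, samples):
        t = self._one_site(samples, Y_PATTERN)
        assert find_y_specific(t, MALES, FEMALES) == {("chrXIX", 100)}

    def test_one_male_homref_excludes(self, samples):
        pattern = _interleave([HET, HET, HET, HOM_REF], [HOM_REF] * 4)
        t = self._one_site(samples, pattern)
        assert find_y_specific(t, MALES, FEMALES) == set()

    def test_missing_female_excludes(self, samples):
        pattern = _interleave([HET] * 4, [HOM_REF, HOM_REF, HOM_REF, MISSING])
        t = self._one_site(samples, pattern)
        assert find_y_specific(t, MALES, FEMALES) == set()

    def test_female_hom_alt_depends_on_rule(self, samples):
        pattern = _interleave([HET] * 4, [HOM_REF, HOM_REF, HOM_ALT, HOM_REF])
        t = self._one_site(samples, pattern)
        assert find_y_specific(t, MALES, FEMALES, "any_hom") == {("chrXIX", 100)}
        assert find_y_specific(t, MALES, FEMALES, "hom_ref") == set()

    def test_unknown_sample_errors(self, samples):
        t = self._one_site(samples, Y_PATTERN)
        with pytest.raises(GenotypeTableError):
            find_y_specific(t, MALES + ["ghost"], FEMALES)

    def test_thresholds_anti_monotone(self, small_noiseless):
        """More stringent quality filtering never adds Y-specific loci."""
        rna = small_noiseless.rna_genotypes
        males = list(rna.samples.index[rna.samples["sex"] == "M"])
        females = list(rna.samples.index[rna.samples["sex"] == "F"])
        prev = None
        for gq_min, pl_min in [(20, 25), (40, 40), (60, 70), (75, 90)]:
            found = find_y_specific(
                filter_genotypes(rna, gq_min, pl_min), males, females
            )
            if prev is not None:
                assert found <= prev
            prev = found


class TestClassification:
    GENE = GeneModel(
        "g1", "chrXIX", 1000, 4000, "+", ((1000, 2000), (3000, 4000))
    )

    def test_rna_sites_mean_transcribed(self):
        call = classify_gene_y_status(
            self.GENE,
            rna_y_sites={("chrXIX", 1500), ("chrXIX", 3500)},
            dna_y_sites={("chrXIX", 1500)},
        )
        assert call.status == "transcribed_Y"
        assert call.n_rna_sites == 2

    def test_no_evidence_means_hemizygous(self):
        call = classify_gene_y_status(self.GENE, set(), set())
        assert call.status == "hemizygous"

    def test_dna_exonic_only_means_silenced(self):
        call = classify_gene_y_status(self.GENE, set(), {("chrXIX", 1200)})
        assert call.status == "silenced_Y"

    def test_dna_intron_only_means_ambiguous(self):
        call = classify_gene_y_status(self.GENE, set(), {("chrXIX", 2500)})
        assert call.status == "ambiguous"
        assert call.n_dna_intronic == 1

    def test_sites_outside_gene_ignored(self):
        call = classify_gene_y_status(
            self.GENE, {("chrXIX", 99), ("chr1", 1500)}, {("chrXIX", 4000)}
        )
        assert call.status == "hemizygous"

    def test_min_informative_sites_gate(self):
        call = classify_gene_y_status(
            self.GENE, {("chrXIX", 1500)}, set(), min_informative_sites=2
        )
        assert call.status == "hemizygous"


class TestTabulate:
    def test_counting(self):
        calls = [
            classify_gene_y_status(
                GeneModel(g, "chrXIX", 0, 10, "+", ((0, 10),)), rna, dna
            )
            for g, rna, dna in [
                ("A", set(), set()),
                ("B", set(), {("chrXIX", 5)}),
                ("C", {("chrXIX", 5)}, set()),
            ]
        ]
        comp = pd.Series({"A": "stratum_II", "B": "stratum_II", "C": "stratum_II"})
        table = tabulate_y_status(calls, comp)
        row = table[table["compartment"] == "stratum_II"].iloc[0]
        assert row["n_X_linked"] == 2 and row["n_transcribed_Y"] == 1

    def test_statuses_partition_genes(self, small_noiseless):
        from dosagecomp.report import classify_from_tables

        ds = small_noiseless
        calls, _, _ = classify_from_tables(
            ds.genes, ds.region_maps, ds.rna_genotypes, ds.dna_genotypes
        )
        comp = ds.truth["compartment"]
        table = tabulate_y_status(calls, comp)
        total = table[table["compartment"] == "total"].iloc[0]
        n_status = sum(
            total[f"n_{s}"]
            for s in ("transcribed_Y", "hemizygous", "silenced_Y", "ambiguous")
        )
        assert n_status == len(calls)

    def test_duplicate_gene_ids_rejected(self):
        g = GeneModel("A", "chrXIX", 0, 10, "+", ((0, 10),))
        calls = [classify_gene_y_status(g, set(), set())] * 2
        with pytest.raises(ValueError):
            tabulate_y_status(calls, pd.Series({"A": "PAR"}))

    def test_empty_input(self):
        table = tabulate_y_status([], pd.Series(dtype=object))
        assert (table.drop(columns="compartment").to_numpy() == 0).all()
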