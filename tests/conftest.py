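import numpy as np
import pandas as pd
import pytest

from dosagecomp.simulate import SimulationConfig, simulate_dataset
from dosagecomp.y_status import GenotypeTable


def make_genotype_table(records, samples):
    """Build a GenotypeTable from compact per-site dicts.

    Each record: (chrom, pos, ref, alts, genotypes, gq, pl_margin) with
    per-sample lists; samples is a list of (id, sex, assay).
    """
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], tuple(r[3])) for r in records],
        columns=["chrom", "pos", "ref", "alts"],
    )
    n_samples = len(samples)
    gts = (
        np.array([r[4] for r in records], dtype=np.int8)
        if records
        else np.zeros((0, n_samples), np.int8)
    )
    gq = (
        np.array([r[5] for r in records], dtype=float)
        if records
        else np.zeros((0, n_samples))
    )
    pl = (
        np.array([r[6] for r in records], dtype=float)
        if records
        else np.zeros((0, n_samples))
    )
    meta = pd.DataFrame(
        {"sex": [s[1] for s in samples], "assay": [s[2] for s in samples]},
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    return GenotypeTable(sites=sites, genotypes=gts, gq=gq, pl_margin=pl, samples=meta)


@pytest.fixture(scope="session")
def small_noiseless():
    """A small no-noise dataset: quality never drops a call, no sex-biased
    genes, so classification and ratios are fully determined by truth."""
    cfg = SimulationConfig(
        n_autosomal_genes=300,
        n_par_genes=30,
        n_stratum_i_genes=60,
        n_stratum_ii_genes=60,
        frac_sex_biased=0.0,
        low_quality_fraction=0.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rna_samples8():
    return [(f"pop{p}_{s}", s, "RNA") for p in range(1, 5) for s in ("M", "F")]
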