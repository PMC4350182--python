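"""Count normalisation, sex-differential expression, and FPKM.

The sex contrast is a two-group negative-binomial Wald test on library-size
normalised counts: median-of-ratios size factors, a per-gene
method-of-moments dispersion estimate with a floor, and a delta-method
standard error for the log2 fold change, followed by Benjamini–Hochberg
correction across all tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


class NormalizationError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene × sample matrix of raw read counts with sample metadata.

    ``counts`` is indexed by gene id with sample-id columns; ``samples``
    is indexed by sample id with at least a ``sex`` column ({M, F}), and
    typically ``population`` and ``assay``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if not set(self.counts.columns) <= set(self.samples.index):
            unknown = set(self.counts.columns) - set(self.samples.index)
            raise ValueError(f"samples without metadata: {sorted(unknown)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def sex_samples(self, sex: str) -> list[str]:
        ids = self.samples.index[self.samples["sex"] == sex]
        return [s for s in self.counts.columns if s in set(ids)]


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Per gene with no zero count, the geometric mean across samples is a
    pseudo-reference; a sample's factor is the median over those genes of
    its count over the reference.  Fails when no gene is nonzero in every
    sample.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no gene with nonzero counts in all samples")
    ref = mat[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _mom_dispersion(norm_m: np.ndarray, norm_f: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by method of moments, floored.

    Uses the within-sex pooled residual variance (so a genuine sex effect
    is not mistaken for overdispersion) against the overall normalised
    mean: alpha = max((s2 - mbar) / mbar^2, floor).
    """
    n_m, n_f = norm_m.shape[1], norm_f.shape[1]
    ss = ((norm_m - norm_m.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (norm_f - norm_f.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / (n_m + n_f - 2)
    mbar = np.concatenate([norm_m, norm_f], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mbar) / np.square(mbar)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_sex_test(counts: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene NB Wald test of male vs. female expression.

    Genes with all-zero counts are dropped before testing (and before the
    BH correction).  Returns a frame indexed by gene id with columns
    ``base_mean``, ``log2fc`` (male over female), ``pvalue``, ``padj`` and
    ``bias`` in {male, female, none}; a gene is called biased iff its
    BH-adjusted p value is below ``alpha``.
    """
    males = counts.sex_samples("M")
    females = counts.sex_samples("F")
    if len(males) < 2 or len(females) < 2:
        raise DesignError(
            f"need >=2 samples per sex, got {len(males)} male / {len(females)} female"
        )
    sf = size_factors(counts)
    tested = counts.counts.loc[counts.counts.sum(axis=1) > 0]
    norm = tested.to_numpy(dtype=float) / sf.loc[tested.columns].to_numpy()
    col = {s: i for i, s in enumerate(tested.columns)}
    norm_m = norm[:, [col[s] for s in males]]
    norm_f = norm[:, [col[s] for s in females]]

    m_m = norm_m.mean(axis=1)
    m_f = norm_f.mean(axis=1)
    disp = _mom_dispersion(norm_m, norm_f)

    mm = m_m + LOG2FC_PSEUDOCOUNT
    mf = m_f + LOG2FC_PSEUDOCOUNT
    log2fc = np.log2(mm / mf)
    # delta method: Var(log2 Xbar) ~ Var(Xbar) / (Xbar ln2)^2, NB variance m + a m^2
    ln2sq = np.log(2.0) ** 2
    var_m = (mm + disp * mm**2) / len(males)
    var_f = (mf + disp * mf**2) / len(females)
    se = np.sqrt(var_m / (mm**2 * ln2sq) + var_f / (mf**2 * ln2sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    _, padj, _, _ = multipletests(pvalue, method="fdr_bh")

    bias = np.where(
        padj < alpha, np.where(log2fc > 0, "male", "female"), "none"
    )
    # exactly zero fold change cannot be a biased call even at padj ~ 0
    bias = np.where(log2fc == 0.0, "none", bias)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "bias": bias,
        },
        index=tested.index,
    )


def fpkm(counts: CountMatrix | pd.DataFrame, exonic_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM[g, s] = count[g, s] / (len[g]/1e3) / (total[s]/1e6)`` with the
    per-sample total taken as the column sum of the count matrix.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = exonic_lengths.reindex(df.index)
    if lengths.isna().any():
        missing = df.index[lengths.isna()].tolist()
        raise ValueError(f"no exonic length for gene(s): {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise NormalizationError(f"zero total counts in sample(s): {bad}")
    return df.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def fold_change_summary(
    results: pd.DataFrame, compartment: str, bias: str
) -> tuple[int, float, float]:
    """(n, mean, SD) of log2 fold changes for one compartment and bias.

    ``results`` must carry a ``compartment`` column in addition to the
    :func:`nb_sex_test` output.  SD uses the n-1 denominator; mean and SD
    are NaN when undefined (n = 0, or n = 1 for the SD).
    """
    if "compartment" not in results.columns:
        raise ValueError("results must be annotated with a 'compartment' column")
    sel = results[(results["compartment"] == compartment) & (results["bias"] == bias)]
    n = len(sel)
    if n == 0:
        return 0, float("nan"), float("nan")
    mean = float(sel["log2fc"].mean())
    sd = float(sel["log2fc"].std(ddof=1)) if n > 1 else float("nan")
    return n, mean, sd
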