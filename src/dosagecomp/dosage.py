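"""Region-vs-autosome expression ratios with a pooled-bootstrap null.

The statistic is the ratio of the median per-gene expression level in a
sex-chromosome region to the median over all autosomal genes, computed per
sex.  Significance is assessed against a null distribution obtained by
pooling the two gene sets and repeatedly resampling region-sized and
autosome-sized sets with replacement from the pool: under no region effect
the observed ratio behaves like a pooled resample, so an observed value
outside the equitailed percentile interval of the null ratios is evidence
of a genuine regional shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GeneModel, RegionMap, assign_gene_compartment
from .y_status import YStatusCall, x_linked_gene_ids

DEFAULT_B = 10_000
DEFAULT_CONF = 0.95
FPKM_MIN = 1.0


class EmptySetError(ValueError):
    pass


@dataclass(frozen=True)
class RatioResult:
    """Observed ratio of medians with its pooled-bootstrap null interval."""

    region: str
    sex: str
    gene_set: str  # "all" or "X_linked"
    n_region: int
    n_autosome: int
    observed: float
    ci_lower: float
    ci_upper: float
    conf: float
    B: int
    p_value: float
    significant: bool
    seed: int

    @property
    def stars(self) -> str:
        """Graded significance code derived from the empirical p value."""
        if not self.significant:
            return "NS"
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "NS"


def expression_values(
    fpkm: pd.DataFrame,
    sample_ids: list[str],
    gene_ids: list[str] | pd.Index | None = None,
    fpkm_min: float = FPKM_MIN,
    combine: str = "mean",
) -> pd.Series:
    """Per-gene expression level for one sex: mean FPKM over its samples.

    Pools a sex's samples into one value per gene (``combine`` may be
    ``"mean"`` or ``"median"`` across samples) and removes genes whose
    value falls below ``fpkm_min`` — lowly expressed and inactive genes
    carry no dosage information.
    """
    if not sample_ids:
        raise ValueError("need at least one sample")
    sub = fpkm[list(sample_ids)]
    if gene_ids is not None:
        sub = sub.loc[sub.index.intersection(pd.Index(gene_ids))]
    if combine == "mean":
        values = sub.mean(axis=1)
    elif combine == "median":
        values = sub.median(axis=1)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return values[values >= fpkm_min]


def median_ratio(region_values: np.ndarray, autosome_values: np.ndarray) -> float:
    """median(region) / median(autosome); even n uses the central-pair mean."""
    region_values = np.asarray(region_values, dtype=float)
    autosome_values = np.asarray(autosome_values, dtype=float)
    if region_values.size == 0 or autosome_values.size == 0:
        raise EmptySetError("median_ratio needs non-empty value sets")
    denom = float(np.median(autosome_values))
    if denom == 0.0:
        raise ZeroDivisionError("autosomal median is zero")
    return float(np.median(region_values)) / denom


def pooled_bootstrap_null(
    region_values: np.ndarray,
    autosome_values: np.ndarray,
    B: int = DEFAULT_B,
    conf: float = DEFAULT_CONF,
    seed: int = 0,
    region: str = "",
    sex: str = "",
    gene_set: str = "all",
    method: str = "pooled",
) -> RatioResult:
    """Ratio of medians with an equitailed percentile bootstrap interval.

    ``method="pooled"`` (default) draws both resamples from the pooled
    values, giving the null distribution of the ratio under no region
    effect; the observed ratio is significant when it falls outside the
    interval.  ``method="stratified"`` resamples each set from itself,
    yielding an interval around the observed ratio instead.

    The empirical two-sided p is twice the smaller tail fraction of null
    ratios at or beyond the observed value, each tail with the
    (k+1)/(B+1) continuity correction.
    """
    region_values = np.asarray(region_values, dtype=float)
    autosome_values = np.asarray(autosome_values, dtype=float)
    if region_values.size == 0 or autosome_values.size == 0:
        raise EmptySetError("bootstrap needs non-empty value sets")
    if B < 1:
        raise ValueError("B must be >= 1")
    if method not in ("pooled", "stratified"):
        raise ValueError(f"unknown method {method!r}")

    observed = median_ratio(region_values, autosome_values)
    n_r, n_a = region_values.size, autosome_values.size
    rng = np.random.default_rng(seed)

    if method == "pooled":
        src_r = src_a = np.concatenate([region_values, autosome_values])
    else:
        src_r, src_a = region_values, autosome_values
    med_r = np.median(src_r[rng.integers(0, src_r.size, size=(B, n_r))], axis=1)
    med_a = np.median(src_a[rng.integers(0, src_a.size, size=(B, n_a))], axis=1)
    ratios = med_r / med_a

    tail = (1.0 - conf) / 2.0
    ci_lower, ci_upper = np.quantile(ratios, [tail, 1.0 - tail])
    # two-sided empirical p with (k+1)/(B+1) continuity correction per tail;
    # ties count in both tails so a degenerate null gives p = 1, not 0
    k_le = int(np.sum(ratios <= observed))
    k_ge = int(np.sum(ratios >= observed))
    p = min(1.0, 2.0 * min((k_le + 1) / (B + 1), (k_ge + 1) / (B + 1)))
    significant = bool(observed < ci_lower or observed > ci_upper)
    return RatioResult(
        region=region,
        sex=sex,
        gene_set=gene_set,
        n_region=n_r,
        n_autosome=n_a,
        observed=observed,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        conf=conf,
        B=B,
        p_value=p,
        significant=significant,
        seed=seed,
    )


def run_dosage_analysis(
    fpkm: pd.DataFrame,
    genes: list[GeneModel],
    region_maps: dict[str, RegionMap],
    y_calls: list[YStatusCall],
    samples: pd.DataFrame,
    B: int = DEFAULT_B,
    conf: float = DEFAULT_CONF,
    seed: int = 0,
    fpkm_min: float = FPKM_MIN,
) -> list[RatioResult]:
    """Full region × sex dosage analysis against the autosomal baseline.

    For each sex, computes the all-genes ratio for the whole sex
    chromosome and each of its compartments, plus the X-linked-restricted
    ratio (hemizygous + silenced-Y genes) for each stratum.  The same
    X-linked gene set is used for both sexes so the female values probe
    whether male compensation spills over.  With a PAR and two strata
    this yields 12 results.
    """
    sex_chrom = [c for c, rm in region_maps.items()
                 if any(lbl != "autosome" for lbl, _, _ in rm.compartments)]
    comp = {
        g.gene_id: assign_gene_compartment(region_maps[g.chromosome], g)
        for g in genes
        if g.chromosome in region_maps
    }
    autosomal = [gid for gid, c in comp.items() if c == "autosome"]
    sex_gene_ids = {
        c: [gid for gid, lab in comp.items() if lab == c]
        for c in ("PAR", "stratum_I", "stratum_II")
    }
    whole = [gid for c in sex_chrom for g in genes
             if g.chromosome == c for gid in [g.gene_id]]
    x_linked = x_linked_gene_ids(y_calls)

    results: list[RatioResult] = []
    rng = np.random.default_rng(seed)
    for sex in ("M", "F"):
        ids = samples.index[samples["sex"] == sex]
        sample_ids = [s for s in fpkm.columns if s in set(ids)]
        auto_vals = expression_values(fpkm, sample_ids, autosomal, fpkm_min)
        targets: list[tuple[str, str, list[str]]] = [
            ("XIX", "all", whole),
            ("PAR", "all", sex_gene_ids["PAR"]),
            ("stratum_I", "all", sex_gene_ids["stratum_I"]),
            ("stratum_II", "all", sex_gene_ids["stratum_II"]),
            ("stratum_I", "X_linked",
             [g for g in sex_gene_ids["stratum_I"] if g in x_linked]),
            ("stratum_II", "X_linked",
             [g for g in sex_gene_ids["stratum_II"] if g in x_linked]),
        ]
        for region, gene_set, gids in targets:
            reg_vals = expression_values(fpkm, sample_ids, gids, fpkm_min)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            results.append(
                pooled_bootstrap_null(
                    reg_vals.to_numpy(),
                    auto_vals.to_numpy(),
                    B=B,
                    conf=conf,
                    seed=sub_seed,
                    region=region,
                    sex=sex,
                    gene_set=gene_set,
                )
            )
    return results


def results_table(results: list[RatioResult]) -> pd.DataFrame:
    """Tabular view of dosage results (one row per contrast)."""
    return pd.DataFrame(
        [
            {
                "contrast": f"{'XY' if r.sex == 'M' else 'XX'}"
                f"{'male' if r.sex == 'M' else 'female'}:AA {r.region}",
                "region": r.region,
                "sex": r.sex,
                "gene_set": r.gene_set,
                "observed": r.observed,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p": r.p_value,
                "stars": r.stars,
                "n_region": r.n_region,
                "n_autosome": r.n_autosome,
                "B": r.B,
                "seed": r.seed,
            }
            for r in results
        ]
    )
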