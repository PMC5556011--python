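"""Cell-type specificity calls against a 4-type reference and DE-list enrichment.

The reference count matrix (neurons, microglia, oligodendrocytes,
astrocytes; replicates per type) is normalized by median-of-ratios size
factors; a gene is called type-specific when its per-type replicate mean of
normalized counts exceeds 10 in exactly one type and stays below 1 in every
other type.  Enrichment of specificity classes in a DE list is a one-sided
Fisher's exact (hypergeometric) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

HI_THRESHOLD = 10.0
LO_THRESHOLD = 1.0


def size_factors_median_of_ratios(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For genes with nonzero counts in every sample, factor_j is the median of
    c_gj / geometric-mean_g over those genes.
    """
    x = counts.values.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; cannot form the "
            "reference (consider a pseudo-reference with a pseudocount)"
        )
    sub = x[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_median_of_ratios(counts: ExpressionMatrix) -> pd.DataFrame:
    """Counts divided per sample by their median-of-ratios size factor."""
    return counts.values / size_factors_median_of_ratios(counts)


def call_specific_genes(
    counts: ExpressionMatrix,
    type_labels: pd.Series,
    hi: float = HI_THRESHOLD,
    lo: float = LO_THRESHOLD,
    normalize: bool = True,
) -> pd.DataFrame:
    """Call cell-type-specific genes on (normalized) per-type replicate means.

    Thresholds are strict: mean > hi in the calling type, mean < lo in every
    other type.  Returns a per-gene table with the call (or None), the mean
    in the called type and the max mean elsewhere.
    """
    if lo >= hi:
        raise ValueError("lo threshold must be below hi threshold")
    missing = set(counts.sample_ids) - set(type_labels.index)
    if missing:
        raise ValueError(f"samples without a cell-type label: {sorted(missing)}")
    values = (
        normalize_median_of_ratios(counts) if normalize else counts.values.astype(float)
    )
    types = sorted(type_labels.unique())
    means = pd.DataFrame(
        {
            t: values[[s for s in counts.sample_ids if type_labels[s] == t]].mean(axis=1)
            for t in types
        }
    )
    arr = means.to_numpy()
    order = np.argsort(-arr, axis=1)
    top = order[:, 0]
    top_mean = arr[np.arange(len(arr)), top]
    other_max = np.where(
        arr.shape[1] > 1,
        np.partition(arr, -2, axis=1)[:, -2],
        -np.inf,
    )
    qualifies = (top_mean > hi) & (other_max < lo)
    # a second qualifying type would need another mean > hi, but every
    # non-top mean of a qualifying gene is < lo < hi
    assert not ((arr > hi).sum(axis=1)[qualifies] > 1).any()
    calls = pd.DataFrame(
        {
            "cell_type": np.where(qualifies, np.array(types, dtype=object)[top], None),
            "mean_in_type": top_mean,
            "max_mean_other": other_max,
        },
        index=counts.gene_ids,
    )
    calls.index.name = "gene_id"
    return calls


@dataclass
class EnrichmentTable2x2:
    """2x2 enrichment table: a = |DE ∩ specific|, with odds ratio and p."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_enrichment(
    de_genes: set[str],
    specific_genes: set[str],
    universe: set[str],
    two_sided: bool = False,
) -> EnrichmentTable2x2:
    """Fisher's exact test for over-representation of a specificity class.

    One-sided toward enrichment by default (hypergeometric upper tail on the
    overlap); two-sided available behind the flag.
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes <= universe or not specific_genes <= universe:
        raise ValueError("de_genes and specific_genes must be subsets of the universe")
    a = len(de_genes & specific_genes)
    b = len(de_genes - specific_genes)
    c = len(specific_genes - de_genes)
    d = len(universe) - a - b - c
    table = [[a, b], [c, d]]
    res = stats.fisher_exact(table, alternative="two-sided" if two_sided else "greater")
    return EnrichmentTable2x2(a, b, c, d, float(res.statistic), float(res.pvalue))


def enrichment_by_class(
    de_table: pd.DataFrame,
    calls: pd.DataFrame,
    direction: str,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of each cell-type class within one DE direction.

    The default universe is the intersection of the DE table's tested genes
    (status != filtered) and the reference's genes — genes observed in both
    datasets — and is recorded in the output for auditability.
    """
    tested = set(de_table.index[de_table["status"] != "filtered"])
    if universe is None:
        universe = tested & set(calls.index)
    de = set(de_table.index[de_table["status"] == direction]) & universe
    rows = []
    for cell_type in sorted(t for t in calls["cell_type"].dropna().unique()):
        spec = set(calls.index[calls["cell_type"] == cell_type]) & universe
        tab = fisher_enrichment(de, spec, universe)
        rows.append(
            {
                "cell_type": cell_type,
                "direction": direction,
                "n_overlap": tab.a,
                "n_de": len(de),
                "n_specific": len(spec),
                "universe": len(universe),
                "odds_ratio": tab.odds_ratio,
                "p": tab.p,
            }
        )
    return pd.DataFrame(rows)
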