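"""Normalization and two-group differential expression.

One moderated-t engine (empirical-Bayes variance shrinkage in the limma
style) serves both the mRNA branch (log2 FPKM + 0.1 after quantile
normalization and the "FPKM > 1 in at least one group" filter) and the small
RNA branch (log2 CPM + 1).  Calls use the study's thresholds: absolute
signed fold-change > 1.5 and BH-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneAnnotation, SampleMetadata

DEFAULT_FC_CUT = 1.5
DEFAULT_ALPHA = 0.05
MRNA_PSEUDO = 0.1  # added to FPKM before log2
SMALLRNA_PSEUDO = 1.0  # added to CPM before log2


# ---------------------------------------------------------------------------
# normalization


def compute_fpkm(counts: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped fragments.

    FPKM_gj = 1e9 * c_gj / (L_g * N_j) with N_j the sample's total count.
    """
    if counts.kind != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    lengths = annotation.lengths_for(counts.gene_ids).to_numpy(dtype=float)
    lib = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"zero library size for sample {bad!r}")
    fpkm = 1e9 * counts.values.to_numpy(dtype=float) / (lengths[:, None] * lib[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.sample_ids), "FPKM"
    )


def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: every sample rescaled to a total of 1e6."""
    if counts.kind != "counts":
        raise ValueError("cpm_normalize expects a counts matrix")
    lib = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[int(np.argmin(lib))]
        raise ValueError(f"zero library size for sample {bad!r}")
    cpm = 1e6 * counts.values.to_numpy(dtype=float) / lib[None, :]
    return ExpressionMatrix(
        pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids), "CPM"
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the cross-sample mean distribution.

    Each sample's sorted vector is replaced by the mean of all samples'
    sorted vectors; tied values receive the mean of the quantile values
    they would have occupied (average-rank convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        matrix.kind,
    )


def group_filter_fpkm(
    fpkm: ExpressionMatrix, metadata: SampleMetadata, threshold: float = 1.0
) -> list[str]:
    """Genes with group-mean FPKM strictly above ``threshold`` in >= 1 group."""
    metadata.check_covers(fpkm)
    case, ctrl = metadata.groups()
    case = [s for s in fpkm.sample_ids if s in set(case)]
    ctrl = [s for s in fpkm.sample_ids if s in set(ctrl)]
    mean_case = fpkm.values[case].mean(axis=1)
    mean_ctrl = fpkm.values[ctrl].mean(axis=1)
    keep = (mean_case > threshold) | (mean_ctrl > threshold)
    return list(fpkm.values.index[keep])


# ---------------------------------------------------------------------------
# fold changes


def log2_fold_change(mean_control: float, mean_case: float, pseudocount: float = 0.0):
    """log2(case / control) of group means; vectorized over array inputs."""
    a = np.asarray(mean_case, dtype=float) + pseudocount
    b = np.asarray(mean_control, dtype=float) + pseudocount
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError(
            "non-positive group mean; supply a pseudocount to take the ratio"
        )
    out = np.log2(a / b)
    return float(out) if out.ndim == 0 else out


def signed_fold_change(log2fc):
    """Signed linear fold change: 2^lfc for lfc >= 0, else -2^(-lfc).

    The negative branch makes the "< -1.5" calling threshold meaningful
    (a halving is -2, not 0.5).
    """
    lfc = np.asarray(log2fc, dtype=float)
    out = np.where(lfc >= 0, np.power(2.0, lfc), -np.power(2.0, -lfc))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# moderated t


@dataclass
class ModeratedTestStats:
    """Per-gene moderated-t machinery with the shared shrinkage prior.

    The posterior variance is the precision-weighted blend
    ``s2_post = (d0*s0_sq + df*s2) / (d0 + df)``; the prior (d0, s0_sq) is
    estimated by moment matching on log sample variances.
    """

    table: pd.DataFrame  # index gene; columns: s2, df, s2_post, t_mod, p_raw
    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on z = log(s2): matching the mean and variance of z against the
    log-F distribution implied by the hierarchical model yields d0 (prior
    degrees of freedom, possibly infinite) and s0_sq (prior variance).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    # unbiased-ish excess variance of e beyond the sampling term trigamma(df/2)
    n = len(e)
    excess = ((e - e_mean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t(
    log_matrix: ExpressionMatrix, metadata: SampleMetadata, d0_override: float | None = None
) -> ModeratedTestStats:
    """Empirical-Bayes moderated two-sample t on a log2-scale matrix.

    With ``d0_override = 0`` the statistic reduces to the ordinary pooled t.
    p-values come from the t distribution with ``df + d0`` degrees of freedom.
    """
    if log_matrix.kind != "log2":
        raise ValueError("moderated_t expects log2-scale input")
    metadata.check_covers(log_matrix)
    case, ctrl = metadata.groups()
    case = [s for s in log_matrix.sample_ids if s in set(case)]
    ctrl = [s for s in log_matrix.sample_ids if s in set(ctrl)]
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")

    x1 = log_matrix.values[case].to_numpy(dtype=float)
    x2 = log_matrix.values[ctrl].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df

    if not (s2 > 0).any():
        warnings.warn(
            "all genes have zero within-group variance; falling back to "
            "exact-equality calls (p = 0 where group means differ, 1 otherwise)"
        )
        diff = m1 - m2
        p = np.where(diff == 0, 1.0, 0.0)
        table = pd.DataFrame(
            {"s2": s2, "df": float(df), "s2_post": s2, "t_mod": np.where(diff == 0, 0.0, np.inf) * np.sign(diff), "p_raw": p},
            index=log_matrix.gene_ids,
        )
        return ModeratedTestStats(table, 0.0, 0.0)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if d0 > 0 else 0.0
    else:
        d0, s0_sq = estimate_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, (m1 - m2) / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # zero-variance genes with a real mean difference are off the model; call
    # them by exact equality
    degenerate = (se == 0) & (m1 != m2)
    p = np.where(degenerate, 0.0, p)

    table = pd.DataFrame(
        {"s2": s2, "df": float(df), "s2_post": s2_post, "t_mod": t_mod, "p_raw": p},
        index=log_matrix.gene_ids,
    )
    return ModeratedTestStats(table, d0, s0_sq)


# ---------------------------------------------------------------------------
# multiple testing and calling


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame,
    fc_cut: float = DEFAULT_FC_CUT,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Attach over/under/ns status from signed fold-change and adjusted p.

    ``results`` needs columns ``fold_change`` and ``p_adj``; the thresholds
    are strict: over means fold_change > fc_cut and p_adj < alpha, under
    means fold_change < -fc_cut and p_adj < alpha.
    """
    out = results.copy()
    over = (out["fold_change"] > fc_cut) & (out["p_adj"] < alpha)
    under = (out["fold_change"] < -fc_cut) & (out["p_adj"] < alpha)
    out["status"] = np.where(over, "over", np.where(under, "under", "ns"))
    return out


@dataclass
class DEOptions:
    fc_cut: float = DEFAULT_FC_CUT
    alpha: float = DEFAULT_ALPHA
    fpkm_filter: float = 1.0
    quantile: bool = True
    pseudocount: float | None = None  # for fold changes on zero means


def run_de_mrna(
    counts: ExpressionMatrix,
    annotation: GeneAnnotation,
    metadata: SampleMetadata,
    options: DEOptions | None = None,
) -> pd.DataFrame:
    """Full mRNA branch: FPKM -> quantile norm -> group filter -> moderated t.

    Returns a per-gene table (filtered genes carry status "filtered" and NaN
    statistics; the BH universe is the post-filter set only).
    """
    opt = options or DEOptions()
    fpkm = compute_fpkm(counts, annotation)
    if opt.quantile:
        fpkm = quantile_normalize(fpkm)
    kept = group_filter_fpkm(fpkm, metadata, opt.fpkm_filter)
    return _de_core(fpkm, metadata, kept, MRNA_PSEUDO, opt)


def run_de_smallrna(
    counts: ExpressionMatrix,
    metadata: SampleMetadata,
    options: DEOptions | None = None,
) -> pd.DataFrame:
    """Small RNA branch: CPM (per-million) -> log2(CPM+1) -> moderated t."""
    opt = options or DEOptions()
    cpm = cpm_normalize(counts)
    return _de_core(cpm, metadata, cpm.gene_ids, SMALLRNA_PSEUDO, opt)


def _de_core(
    normed: ExpressionMatrix,
    metadata: SampleMetadata,
    kept: list[str],
    log_pseudo: float,
    opt: DEOptions,
) -> pd.DataFrame:
    case, ctrl = metadata.groups()
    case = [s for s in normed.sample_ids if s in set(case)]
    ctrl = [s for s in normed.sample_ids if s in set(ctrl)]
    mean_case = normed.values[case].mean(axis=1)
    mean_ctrl = normed.values[ctrl].mean(axis=1)

    sub = normed.subset_genes(kept)
    logm = ExpressionMatrix(np.log2(sub.values + log_pseudo), "log2")
    mstats = moderated_t(logm, metadata)
    p_adj = bh_adjust(mstats.table["p_raw"].to_numpy())

    pseudo = opt.pseudocount or 0.0
    lfc = log2_fold_change(
        mean_ctrl.loc[kept].to_numpy(), mean_case.loc[kept].to_numpy(), pseudo
    )
    tested = pd.DataFrame(
        {
            "mean_control": mean_ctrl.loc[kept],
            "mean_case": mean_case.loc[kept],
            "log2fc": lfc,
            "fold_change": signed_fold_change(lfc),
            "p_raw": mstats.table["p_raw"].to_numpy(),
            "p_adj": p_adj,
        },
        index=kept,
    )
    tested = call_de(tested, opt.fc_cut, opt.alpha)

    dropped = [g for g in normed.gene_ids if g not in set(kept)]
    if dropped:
        filt = pd.DataFrame(
            {
                "mean_control": mean_ctrl.loc[dropped],
                "mean_case": mean_case.loc[dropped],
                "log2fc": np.nan,
                "fold_change": np.nan,
                "p_raw": np.nan,
                "p_adj": np.nan,
                "status": "filtered",
            },
            index=dropped,
        )
        tested = pd.concat([tested, filt])
    tested.index.name = "gene_id"
    return tested.loc[normed.gene_ids]


def tally_small_rna_classes(
    de_table: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Count over/under calls per small-RNA class (miRNA, snRNA, snoRNAs, ...)."""
    classes = annotation.table.reindex(de_table.index)["rna_class"]
    known = {"mRNA", "miRNA", "snRNA", "snoRNA_CD", "snoRNA_HACA", "snoRNA_orphan", "scaRNA", "other"}
    unknown = set(classes.dropna()) - known
    if unknown:
        warnings.warn(f"unknown small-RNA classes bucketed as 'other': {sorted(unknown)}")
    classes = classes.where(classes.isin(known), "other").fillna("other")
    rows = []
    for cls in sorted(classes.unique()):
        sub = de_table[classes == cls]
        rows.append(
            {
                "rna_class": cls,
                "n_over": int((sub["status"] == "over").sum()),
                "n_under": int((sub["status"] == "under").sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["rna_class", "n_over", "n_under"]
    ).set_index("rna_class")
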