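"""Weighted gene co-expression network built from scratch.

The pipeline follows the classic weighted-network recipe: rank genes by
median absolute deviation and keep the most variable, form the pairwise
Spearman correlation matrix, raise |rho| to a soft power chosen so the
network's connectivity distribution is approximately scale-free, convert the
adjacency to a topological overlap matrix (TOM), cluster genes by
average-linkage hierarchical clustering on 1 - TOM, cut the tree into
modules of at least ``min_size`` genes, and summarize each module by its
eigengene (first principal component of the standardized module submatrix)
and the per-gene module membership kME.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .io import ExpressionMatrix, GeneSet

DEFAULT_TOP_K = 10000
DEFAULT_MIN_SIZE = 100
DEFAULT_CUT_HEIGHT = 0.99
DEFAULT_R2_THRESHOLD = 0.80


# ---------------------------------------------------------------------------
# gene selection and correlation


def select_top_variable(matrix: ExpressionMatrix, k: int = DEFAULT_TOP_K) -> ExpressionMatrix:
    """Keep the k genes with the largest median absolute deviation.

    Ties in MAD are broken lexicographically by gene ID; the output keeps
    MAD-descending order.  k >= n_genes returns all genes.
    """
    x = matrix.values.to_numpy(dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    order = sorted(range(len(mad)), key=lambda i: (-mad[i], matrix.gene_ids[i]))
    chosen = [matrix.gene_ids[i] for i in order[: min(k, len(order))]]
    return matrix.subset_genes(chosen)


def spearman_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlations (Pearson on average ranks).

    Zero-variance genes have undefined correlations; their rows/columns are
    set to 0 (diagonal stays 1) with a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    x = matrix.values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlations set to 0"
        )
        # give constant rows harmless variance for the corrcoef call
        ranks = ranks.copy()
        ranks[constant] += np.linspace(0, 1, ranks.shape[1])
    rho = np.corrcoef(ranks)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=matrix.gene_ids, columns=matrix.gene_ids)


# ---------------------------------------------------------------------------
# soft power and adjacency


@dataclass
class SoftPowerScan:
    """Scale-free-fit R^2 and mean connectivity per candidate power."""

    table: pd.DataFrame  # index beta; columns: r_squared, slope, mean_connectivity
    chosen: int
    r2_threshold: float


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log10 p(k) vs log10 k regression.

    Connectivities are split into ``n_bins`` equal-occupancy bins; within
    each bin the mean k and the empirical density (bin frequency divided by
    bin width, since equal-occupancy bins have constant frequency) form one
    point of the log-log fit.  Returns (nan, nan) when the fit is
    degenerate.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return np.nan, np.nan
    edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 4:
        return np.nan, np.nan
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        members = k[idx == b]
        width = edges[b + 1] - edges[b]
        if members.size == 0 or width <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / (k.size * width)))
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        return np.nan, np.nan
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2), float(res.slope)


def pick_soft_power(
    rho: pd.DataFrame,
    powers: range = range(1, 21),
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    n_bins: int = 10,
) -> SoftPowerScan:
    """Choose the smallest power whose scale-free fit reaches the threshold.

    If no power reaches it, the power with the best R^2 is chosen with a
    warning.  Degenerate powers (undefined fit) are skipped.
    """
    a = np.abs(rho.to_numpy(dtype=float))
    rows = []
    for beta in powers:
        adj = a**beta
        k = adj.sum(axis=1) - 1.0  # exclude the self-edge
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        if np.isnan(r2):
            warnings.warn(f"power {beta}: degenerate connectivity, skipped")
        rows.append(
            {
                "beta": beta,
                "r_squared": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows).set_index("beta")
    ok = table["r_squared"].dropna()
    reaching = ok[ok >= r2_threshold]
    if len(reaching):
        chosen = int(reaching.index[0])
    else:
        if ok.empty:
            raise ValueError("scale-free fit undefined for every candidate power")
        chosen = int(ok.idxmax())
        warnings.warn(
            f"no power reaches R^2 >= {r2_threshold}; using argmax beta={chosen}"
        )
    return SoftPowerScan(table, chosen, r2_threshold)


def adjacency(rho: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency.

    Unsigned (default): a_ij = |rho_ij|^beta.  Signed: ((1+rho)/2)^beta.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = rho.to_numpy(dtype=float)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=rho.index, columns=rho.columns)


# ---------------------------------------------------------------------------
# topological overlap and module detection


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """TOM: omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    l_ij sums shared-neighbor weight over u != i, j; the diagonal is set
    to 1.  Computed by matrix product with the self-edge correction.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # includes u = i and u = j terms only through zeroed diagonal
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Average-linkage tree on 1 - TOM, cut statically at ``cut_height``.

    Branches with at least ``min_size`` genes become modules, numbered 1, 2,
    ... by decreasing size (ties broken by smallest member gene ID); all
    remaining genes get label 0 (unassigned).
    """
    genes = list(tom.index)
    n = len(genes)
    if min_size > n:
        warnings.warn("min_size exceeds the gene count; all genes unassigned")
        return pd.Series(0, index=genes, name="module")
    d = 1.0 - tom.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    big = sizes[sizes >= min_size]
    ordered = sorted(
        big.index, key=lambda c: (-big[c], min(labels.index[labels == c]))
    )
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    out = labels.map(lambda c: remap.get(c, 0)).astype(int)
    out.name = "module"
    return out


# ---------------------------------------------------------------------------
# eigengenes and membership


@dataclass
class ModuleSet:
    """Module labels plus eigengenes, variance explained and kME."""

    labels: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # module x sample
    variance_explained: pd.Series = field(default_factory=pd.Series)
    kme: pd.DataFrame = field(default_factory=pd.DataFrame)  # gene x module

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def module_eigengene(expr: ExpressionMatrix, labels: pd.Series) -> ModuleSet:
    """First principal component of each module's standardized submatrix.

    Genes are z-scored across samples; the eigengene is the leading right-
    singular direction (unit norm over samples), oriented so the mean
    correlation with member genes is positive; variance explained is
    lambda_1 / sum(lambda).
    """
    x = expr.values.to_numpy(dtype=float)
    samples = expr.sample_ids
    eig = {}
    varexp = {}
    for m in sorted(set(labels.unique()) - {0}):
        members = [g for g in expr.gene_ids if labels.get(g, 0) == m]
        if len(members) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        sub = expr.values.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).all():
            raise ValueError(f"module {m} consists of constant genes")
        keep = sd > 0
        z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        if np.corrcoef(np.vstack([e, z]))[0, 1:].mean() < 0:
            e = -e
        eig[m] = e
        varexp[m] = float(s[0] ** 2 / (s**2).sum())
    mset = ModuleSet(
        labels=labels,
        eigengenes=pd.DataFrame(eig, index=samples).T.sort_index(),
        variance_explained=pd.Series(varexp).sort_index(),
    )
    mset.kme = module_membership(expr, mset.eigengenes)
    return mset


def module_membership(expr: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of each gene's profile with each eigengene.

    Constant genes get kME 0 with a warning.
    """
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): kME set to 0")
    xc = x - x.mean(axis=1, keepdims=True)
    safe_sd = np.where(constant, 1.0, sd)
    out = {}
    n = x.shape[1]
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        ec = e - e.mean()
        denom = safe_sd * ec.std(ddof=0) * n
        r = (xc @ ec) / denom
        r[constant] = 0.0
        out[m] = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(out, index=expr.gene_ids)


# ---------------------------------------------------------------------------
# gene-set over-representation


def module_enrichment(
    labels: pd.Series, gene_sets: list[GeneSet], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each module.

    p-values are BH-adjusted across all (module, set) pairs; empty sets
    (after restriction to the universe) are skipped.
    """
    rows = []
    for m in sorted(set(labels.unique()) - {0}):
        members = set(labels.index[labels == m]) & universe
        for gs in gene_sets:
            setg = set(gs.members) & universe
            if not setg:
                continue
            a = len(members & setg)
            # upper-tail P(X >= a) for X ~ Hypergeom(N, |set|, |module|)
            p = float(
                stats.hypergeom.sf(a - 1, len(universe), len(setg), len(members))
            )
            rows.append(
                {
                    "module": m,
                    "set_id": gs.set_id,
                    "n_overlap": a,
                    "n_module": len(members),
                    "n_set": len(setg),
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def build_network(
    expr: ExpressionMatrix,
    top_k: int = DEFAULT_TOP_K,
    powers: range = range(1, 21),
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    signed: bool = False,
) -> tuple[ModuleSet, SoftPowerScan]:
    """Run the whole network stage: selection -> TOM -> modules -> eigengenes."""
    sel = select_top_variable(expr, top_k)
    rho = spearman_matrix(sel)
    scan = pick_soft_power(rho, powers, r2_threshold)
    adj = adjacency(rho, scan.chosen, signed=signed)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, min_size=min_size, cut_height=cut_height)
    mset = module_eigengene(sel, labels)
    return mset, scan
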