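"""miRNA-to-module integration.

Pearson correlation of miRNA expression profiles with module eigengenes
(significance at unadjusted p < 0.05 by default, BH mode available), exact
seed-match target prediction in 3'UTRs (seed = miRNA positions 2-8, minimum
length 7, matched as the reverse complement with U and T equivalent), and
intersection of predicted targets with module membership for the significant
links of the requested direction (negative by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionMatrix

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    return np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))


def correlate_mirna_modules(
    mirna_expr: ExpressionMatrix,
    eigengenes: pd.DataFrame,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Pearson r and p for every (miRNA, module eigengene) pair.

    Samples must be shared and identically ordered.  ``adjust=True``
    BH-adjusts across all pairs before applying ``alpha``.
    """
    if list(mirna_expr.sample_ids) != list(eigengenes.columns):
        raise ValueError("miRNA matrix and eigengenes have mismatched samples")
    n = len(eigengenes.columns)
    if n < 4:
        raise ValueError("need at least 4 shared samples")
    x = mirna_expr.values.to_numpy(dtype=float)
    rows = []
    for m in eigengenes.index:
        e = eigengenes.loc[m].to_numpy(dtype=float)
        ec = e - e.mean()
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum(axis=1) * (ec**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (xc @ ec) / denom, 0.0)
        p = pearson_pvalue(r, n)
        for mirna, ri, pi in zip(mirna_expr.gene_ids, r, p):
            rows.append(
                {
                    "mirna_id": mirna,
                    "module": int(m),
                    "r": float(ri),
                    "p": float(pi),
                    "direction": "negative" if ri < 0 else "positive",
                }
            )
    links = pd.DataFrame(rows)
    pcol = bh_adjust(links["p"].to_numpy()) if adjust else links["p"].to_numpy()
    links["p_effective"] = pcol
    links["significant"] = links["p_effective"] < alpha
    return links


@dataclass
class TargetSite:
    mirna_id: str
    gene_id: str
    position: int  # 0-based start on the UTR, half-open [position, position+seed)
    seed_length: int


def seed_site(mirna_seq: str, min_seed: int = 7) -> str:
    """DNA reverse complement of the miRNA seed (positions 2..1+min_seed)."""
    seed = mirna_seq.upper()[1 : 1 + min_seed]
    return seed.translate(_COMPLEMENT)[::-1]


def predict_targets_seed_match(
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    min_seed: int = 7,
) -> list[TargetSite]:
    """Exact seed matches of each miRNA in each 3'UTR.

    The seed is positions 2..8 of the mature miRNA (5'->3', 1-based),
    extended 3'-ward when ``min_seed > 7``; a site is any exact occurrence of
    the seed's reverse complement in the UTR, with U and T treated as
    equivalent.  miRNAs shorter than ``min_seed + 1`` nt are skipped with a
    warning.  All occurrences are reported with 0-based positions.
    """
    if min_seed < 7:
        raise ValueError("minimum seed length is 7")
    hits: list[TargetSite] = []
    utrs_dna = {uid: s.upper().replace("U", "T") for uid, s in utr_seqs.items()}
    for mid, mseq in mirna_seqs.items():
        if len(mseq) < min_seed + 1:
            warnings.warn(f"miRNA {mid} shorter than {min_seed + 1} nt; skipped")
            continue
        site = seed_site(mseq, min_seed)
        for uid, useq in utrs_dna.items():
            start = 0
            while (pos := useq.find(site, start)) != -1:
                hits.append(TargetSite(mid, uid, pos, min_seed))
                start = pos + 1
    return hits


def predictions_table(hits: list[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id,
                "gene_id": h.gene_id,
                "position": h.position,
                "seed_length": h.seed_length,
            }
            for h in hits
        ],
        columns=["mirna_id", "gene_id", "position", "seed_length"],
    )


def intersect_targets_with_modules(
    links: pd.DataFrame,
    predictions: list[TargetSite] | pd.DataFrame,
    module_labels: pd.Series,
    direction: str = "negative",
) -> list[dict]:
    """(miRNA, module, targets-in-module) for significant links.

    Only links of the requested direction count; targets are the predicted
    target genes that belong to the linked module; empty triples are
    omitted.
    """
    if isinstance(predictions, list):
        predictions = predictions_table(predictions)
    targets_of: dict[str, set[str]] = {
        m: set(sub["gene_id"]) for m, sub in predictions.groupby("mirna_id")
    }
    triples = []
    sig = links[(links["significant"]) & (links["direction"] == direction)]
    for _, row in sig.iterrows():
        members = set(module_labels.index[module_labels == row["module"]])
        targets = sorted(targets_of.get(row["mirna_id"], set()) & members)
        if targets:
            triples.append(
                {
                    "mirna_id": row["mirna_id"],
                    "module": int(row["module"]),
                    "r": float(row["r"]),
                    "p": float(row["p"]),
                    "targets": targets,
                }
            )
    return triples
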