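"""Seeded synthetic datasets with planted ground truth.

Each generator emulates one input of the tuber-transcriptome study design —
a two-group bulk cohort (12 cases vs 10 controls), block-correlated
co-expression modules with anti-correlated miRNAs, a 4-cell-type reference
with 3 replicates per type, and 3'UTR sequences with planted 7-mer seed
sites — and returns, alongside the matrices, a :class:`SyntheticTruth`
recording exactly what was planted, for parameter-recovery tests.

A single global seed fans out to independent per-component RNG streams
(``numpy.random.SeedSequence.spawn``), so adding one component does not
perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, SampleMetadata

DNA = "ACGT"
RNA = "ACGU"
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


class ParameterError(ValueError):
    """Invalid simulation parameters."""


def _revcomp_dna(seq: str) -> str:
    """Reverse complement, always emitting DNA letters (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticTruth:
    """Everything that was planted, keyed the same way the matrices are."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC
    module_of: dict[str, int] = field(default_factory=dict)  # gene -> module (0 = none)
    anti_pairs: list[tuple[str, int, float]] = field(default_factory=list)
    mirna_targets: dict[str, list[str]] = field(default_factory=dict)
    specific_genes: dict[str, str] = field(default_factory=dict)  # gene -> cell type
    planted_sites: list[tuple[str, str, int]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["anti_pairs"] = [list(t) for t in self.anti_pairs]
        d["planted_sites"] = [list(t) for t in self.planted_sites]
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_genes=dict(d.get("de_genes", {})),
            module_of={k: int(v) for k, v in d.get("module_of", {}).items()},
            anti_pairs=[(a, int(b), float(c)) for a, b, c in d.get("anti_pairs", [])],
            mirna_targets={k: list(v) for k, v in d.get("mirna_targets", {}).items()},
            specific_genes=dict(d.get("specific_genes", {})),
            planted_sites=[(a, b, int(c)) for a, b, c in d.get("planted_sites", [])],
        )


# ---------------------------------------------------------------------------
# bulk two-group cohort


@dataclass
class BulkSimParams:
    """Two-group log-normal FPKM cohort with planted fold-changes.

    Defaults mirror the study design: 12 case (tuber) vs 10 control samples.
    ``baseline_log_mean``/``baseline_log_sd`` parameterize the natural-log
    FPKM of an expressed gene; ``noise_sd`` is the per-sample residual SD on
    the log2 scale; planted genes shift the case-group log2 mean by exactly
    ``±log2fc_effect``.
    """

    n_genes: int = 2000
    n_case: int = 12
    n_control: int = 10
    frac_de: float = 0.05
    log2fc_effect: float = 2.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ParameterError("need at least 2 samples per group")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ParameterError("frac_de must lie in [0, 1]")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ParameterError("standard deviations must be non-negative")


def simulate_bulk(
    params: BulkSimParams,
) -> tuple[ExpressionMatrix, GeneAnnotation, SampleMetadata, SyntheticTruth]:
    """Simulate a two-group count matrix whose FPKM round-trips exactly.

    FPKM is simulated first (log-normal baselines, planted log2 shifts,
    Gaussian log2 noise); counts are back-computed via gene lengths and
    per-sample library sizes, ``c = FPKM * L_kb * N / 1e6`` rounded, so
    recomputing FPKM from the counts recovers the simulated surface up to
    rounding.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    rng_gene, rng_noise, rng_lib = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    n = params.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    case_ids = [f"tsc{i:02d}" for i in range(params.n_case)]
    ctrl_ids = [f"ctl{i:02d}" for i in range(params.n_control)]
    samples = case_ids + ctrl_ids

    base_log2 = rng_gene.normal(params.baseline_log_mean, params.baseline_log_sd, n) / np.log(2)
    lengths = rng_gene.integers(500, 5001, n)

    n_de = int(round(params.frac_de * n))
    de_idx = rng_gene.choice(n, size=n_de, replace=False)
    effects = np.zeros(n)
    # alternate signs so up- and down-regulation are both exercised
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    effects[de_idx] = signs * params.log2fc_effect

    log2_fpkm = (
        base_log2[:, None]
        + np.concatenate([effects[:, None].repeat(params.n_case, 1),
                          np.zeros((n, params.n_control))], axis=1)
        + rng_noise.normal(0.0, params.noise_sd, (n, len(samples)))
    )
    fpkm = np.power(2.0, log2_fpkm)

    lib_sizes = rng_lib.integers(15_000_000, 25_000_001, len(samples))
    counts = np.round(fpkm * (lengths[:, None] / 1e3) * (lib_sizes[None, :] / 1e6))

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), "counts"
    )
    ann = GeneAnnotation(
        pd.DataFrame({"length_nt": lengths, "rna_class": "mRNA"}, index=genes)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"group": ["case"] * params.n_case + ["control"] * params.n_control},
            index=samples,
        )
    )
    truth = SyntheticTruth(
        de_genes={genes[i]: float(effects[i]) for i in sorted(de_idx)}
    )
    return matrix, ann, meta, truth


# ---------------------------------------------------------------------------
# correlated co-expression modules + anti-correlated miRNAs


@dataclass
class ModuleSimParams:
    """Latent-factor module structure on the standardized log2 scale.

    Each module m draws one latent factor f_m over samples; a member gene is
    ``sqrt(c) * f_m + sqrt(1-c) * noise`` with ``c = within_module_cor``, so
    the pairwise correlation of two members is analytically c.  Genes beyond
    ``sum(module_sizes)`` are i.i.d. noise.  Each ``anti_pairs`` entry
    (mirna_index, module_index, target_fraction) makes that miRNA a noisy
    negative copy of the module factor and designates the stated fraction of
    the module's genes as planted targets.
    """

    n_genes: int = 500
    module_sizes: Sequence[int] = (120, 120, 120)
    within_module_cor: float = 0.8
    n_samples: int = 22
    n_mirna: int = 6
    anti_pairs: Sequence[tuple[int, int, float]] = ()
    anti_cor: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ParameterError("module sizes exceed n_genes (modules may not overlap)")
        if not 0.0 < self.within_module_cor <= 1.0:
            raise ParameterError("within_module_cor must lie in (0, 1]")
        if self.n_samples < 3:
            raise ParameterError("need at least 3 samples")
        for mi, mod, frac in self.anti_pairs:
            if not 0 <= mi < self.n_mirna:
                raise ParameterError(f"anti-pair miRNA index {mi} out of range")
            if not 1 <= mod <= len(self.module_sizes):
                raise ParameterError(f"anti-pair module index {mod} out of range")
            if not 0.0 <= frac <= 1.0:
                raise ParameterError("target_fraction must lie in [0, 1]")


def simulate_modules(
    params: ModuleSimParams,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate (gene expression, miRNA expression, truth); modules are 1-based."""
    params.validate()
    root = np.random.SeedSequence(params.seed ^ 0x6D6F64)  # distinct stream family
    rng_factor, rng_gene, rng_mirna = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    n, s = params.n_genes, params.n_samples
    genes = [f"g{i:05d}" for i in range(n)]
    samples = [f"s{i:02d}" for i in range(s)]
    mirnas = [f"mir{i:02d}" for i in range(params.n_mirna)]

    factors = rng_factor.normal(size=(len(params.module_sizes), s))
    c = params.within_module_cor
    expr = np.empty((n, s))
    module_of: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(params.module_sizes, start=1):
        noise = rng_gene.normal(size=(size, s))
        expr[pos : pos + size] = np.sqrt(c) * factors[m - 1] + np.sqrt(1 - c) * noise
        for g in genes[pos : pos + size]:
            module_of[g] = m
        pos += size
    expr[pos:] = rng_gene.normal(size=(n - pos, s))
    for g in genes[pos:]:
        module_of[g] = 0

    mirna_expr = rng_mirna.normal(size=(params.n_mirna, s))
    a = params.anti_cor
    anti_pairs: list[tuple[str, int, float]] = []
    mirna_targets: dict[str, list[str]] = {}
    module_genes = {
        m: [g for g in genes if module_of[g] == m]
        for m in range(1, len(params.module_sizes) + 1)
    }
    for mi, mod, frac in params.anti_pairs:
        eps = rng_mirna.normal(size=s)
        mirna_expr[mi] = -np.sqrt(a) * factors[mod - 1] + np.sqrt(1 - a) * eps
        n_targets = int(round(frac * len(module_genes[mod])))
        mirna_targets[mirnas[mi]] = module_genes[mod][:n_targets]
        anti_pairs.append((mirnas[mi], mod, frac))

    gene_matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=samples), "log2"
    )
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mirna_expr, index=mirnas, columns=samples), "log2"
    )
    truth = SyntheticTruth(
        module_of=module_of, anti_pairs=anti_pairs, mirna_targets=mirna_targets
    )
    return gene_matrix, mirna_matrix, truth


# ---------------------------------------------------------------------------
# 4-cell-type single-cell-derived reference


@dataclass
class CellRefSimParams:
    """Reference count matrix with planted cell-type-specific genes.

    Planted genes have mean counts ``hi_mean`` in their own type and
    ``lo_mean`` (< 1) elsewhere; background genes share one mean across all
    types.  With ``noise_sd = 0`` counts are a deterministic even allocation
    of ``floor(mean * replicates)`` reads across replicates, so recovery is
    exact; with ``noise_sd > 0`` counts are Poisson draws around a
    log-normally jittered mean.
    """

    cell_types: Sequence[str] = ("neuron", "microglia", "oligodendrocyte", "astrocyte")
    replicates_per_type: int = 3
    n_genes: int = 200
    n_specific_per_type: int = 5
    hi_mean: float = 50.0
    lo_mean: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.cell_types) != 4:
            raise ParameterError("the reference design uses exactly 4 cell types")
        if self.replicates_per_type < 1:
            raise ParameterError("need at least 1 replicate per type")
        if 4 * self.n_specific_per_type > self.n_genes:
            raise ParameterError("more specific genes than genes")
        if not self.hi_mean > 10:
            raise ParameterError("hi_mean must exceed the >10 calling threshold")
        if not self.lo_mean < 1:
            raise ParameterError("lo_mean must stay below the <1 calling threshold")


def _allocate_counts(mean: float, reps: int) -> np.ndarray:
    """Deterministically spread floor(mean*reps) reads as evenly as possible."""
    total = int(np.floor(mean * reps))
    base, extra = divmod(total, reps)
    out = np.full(reps, base, dtype=float)
    out[:extra] += 1
    return out


def simulate_cell_reference(
    params: CellRefSimParams,
) -> tuple[ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Returns (counts, sample -> cell-type labels, truth)."""
    params.validate()
    root = np.random.SeedSequence(params.seed ^ 0x726566)
    rng_bg, rng_noise = (np.random.default_rng(s) for s in root.spawn(2))

    types = list(params.cell_types)
    reps = params.replicates_per_type
    samples = [f"{t}_{r}" for t in types for r in range(1, reps + 1)]
    genes = [f"g{i:05d}" for i in range(params.n_genes)]

    means = np.empty((params.n_genes, 4))
    specific: dict[str, str] = {}
    k = params.n_specific_per_type
    for t_idx, t in enumerate(types):
        rows = range(t_idx * k, (t_idx + 1) * k)
        for r in rows:
            means[r] = params.lo_mean
            means[r, t_idx] = params.hi_mean
            specific[genes[r]] = t
    n_planted = 4 * k
    bg = np.exp(rng_bg.normal(3.0, 1.0, params.n_genes - n_planted))
    means[n_planted:] = bg[:, None]

    counts = np.empty((params.n_genes, len(samples)))
    for g in range(params.n_genes):
        for t_idx in range(4):
            cols = slice(t_idx * reps, (t_idx + 1) * reps)
            if params.noise_sd == 0:
                counts[g, cols] = _allocate_counts(means[g, t_idx], reps)
            else:
                lam = means[g, t_idx] * np.exp(
                    rng_noise.normal(0.0, params.noise_sd, reps)
                )
                counts[g, cols] = rng_noise.poisson(lam)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), "counts"
    )
    labels = pd.Series(
        [t for t in types for _ in range(reps)], index=samples, name="cell_type"
    )
    return matrix, labels, SyntheticTruth(specific_genes=specific)


# ---------------------------------------------------------------------------
# 3'UTRs with planted miRNA seed sites


@dataclass
class UtrSimParams:
    """Random 3'UTRs with planted 7-mer seed-match sites.

    Each planted site is the reverse complement of the named miRNA's seed
    (positions 2-8) embedded at the stated 0-based offset.  Unless
    ``allow_decoys`` is set, the background sequence is scrubbed of
    accidental sites for every planted miRNA, so a brute-force scan finds
    exactly the planted sites.
    """

    n_utrs: int = 10
    utr_length: int = 300
    utr_ids: Sequence[str] = ()  # explicit UTR names (e.g. gene IDs); overrides n_utrs
    planted_sites: Sequence[tuple[str, str, int]] = ()  # (mirna_id, utr_id, pos)
    mirna_ids: Sequence[str] = ()  # extra / non-planted miRNAs to emit
    mirna_length: int = 22
    alphabet: str = "ACGT"  # UTR alphabet convention; miRNAs always ACGU
    allow_decoys: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.utr_length < 7:
            raise ParameterError("utr_length must allow a 7-mer site")
        if self.alphabet not in ("ACGT", "ACGU"):
            raise ParameterError("alphabet must be 'ACGT' or 'ACGU'")
        if self.mirna_length < 8:
            raise ParameterError("miRNAs must be at least 8 nt")
        for mid, uid, pos in self.planted_sites:
            if pos < 0 or pos + 7 > self.utr_length:
                raise ParameterError(
                    f"site for {mid} in {uid} at {pos} does not fit the UTR"
                )


def simulate_utrs(
    params: UtrSimParams,
) -> tuple[dict[str, str], dict[str, str], SyntheticTruth]:
    """Returns (utr_id -> sequence, mirna_id -> sequence, truth)."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed ^ 0x757472))

    utr_ids = (
        list(params.utr_ids)
        if params.utr_ids
        else [f"utr{i:03d}" for i in range(params.n_utrs)]
    )
    if len(set(utr_ids)) != len(utr_ids):
        raise ParameterError("duplicate UTR IDs")
    known_utrs = set(utr_ids)
    for mid, uid, pos in params.planted_sites:
        if uid not in known_utrs:
            raise ParameterError(f"planted site names unknown UTR {uid!r}")

    planted_mirnas = list(dict.fromkeys(m for m, _, _ in params.planted_sites))
    all_mirnas = planted_mirnas + [
        m for m in params.mirna_ids if m not in planted_mirnas
    ]

    # draw miRNA sequences with pairwise-distinct seeds so site ownership is
    # unambiguous
    mirna_seqs: dict[str, str] = {}
    seeds_seen: set[str] = set()
    for mid in all_mirnas:
        for _ in range(1000):
            seq = "".join(rng.choice(list(RNA), params.mirna_length))
            if seq[1:8] not in seeds_seen:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ParameterError("could not draw miRNAs with distinct seeds")
        seeds_seen.add(seq[1:8])
        mirna_seqs[mid] = seq

    # scrub accidental sites for every emitted miRNA (planted or not) so the
    # predictor's hits coincide with the planted truth exactly
    site_of = {mid: _revcomp_dna(mirna_seqs[mid][1:8]) for mid in all_mirnas}

    sites_by_utr: dict[str, list[tuple[str, int]]] = {u: [] for u in utr_ids}
    for mid, uid, pos in params.planted_sites:
        sites_by_utr[uid].append((mid, pos))
    for uid, sites in sites_by_utr.items():
        occupied: dict[int, str] = {}
        for mid, pos in sites:
            for i, ch in enumerate(site_of[mid]):
                if occupied.get(pos + i, ch) != ch:
                    raise ParameterError(
                        f"conflicting planted sites overlap in {uid} at {pos}"
                    )
                occupied[pos + i] = ch

    utr_seqs: dict[str, str] = {}
    for uid in utr_ids:
        seq = list("".join(rng.choice(list(DNA), params.utr_length)))
        planted_here = {}
        for mid, pos in sites_by_utr[uid]:
            site = site_of[mid]
            seq[pos : pos + 7] = site
            planted_here[(site, pos)] = True
        if not params.allow_decoys and site_of:
            protected = set()
            for mid, pos in sites_by_utr[uid]:
                protected.update(range(pos, pos + 7))
            for _ in range(200):
                dirty = False
                text = "".join(seq)
                for mid, site in site_of.items():
                    start = 0
                    while (hit := text.find(site, start)) != -1:
                        start = hit + 1
                        if (site, hit) in planted_here:
                            continue
                        # mutate one unprotected base inside the accidental site
                        free = [
                            i for i in range(hit, hit + 7) if i not in protected
                        ]
                        if not free:
                            raise ParameterError(
                                f"cannot scrub decoy overlapping planted sites in {uid}"
                            )
                        i = int(rng.choice(free))
                        choices = [b for b in DNA if b != seq[i]]
                        seq[i] = str(rng.choice(choices))
                        dirty = True
                if not dirty:
                    break
            else:  # pragma: no cover
                raise ParameterError(f"decoy scrubbing did not converge for {uid}")
        out = "".join(seq)
        if params.alphabet == "ACGU":
            out = out.replace("T", "U")
        utr_seqs[uid] = out

    truth = SyntheticTruth(
        planted_sites=[(m, u, int(p)) for m, u, p in params.planted_sites]
    )
    return utr_seqs, mirna_seqs, truth


def utr_params_from_module_truth(
    truth: SyntheticTruth,
    all_mirnas: Sequence[str],
    utr_length: int = 300,
    seed: int = 0,
) -> UtrSimParams:
    """Turn planted miRNA->target assignments into UTR simulation parameters.

    One UTR per module gene; each miRNA's designated targets receive one
    planted site at an offset staggered per miRNA so sites never overlap.
    Non-targeting miRNAs are emitted too (their sequences gain no sites).
    """
    genes = sorted(g for g, m in truth.module_of.items() if m != 0)
    mirna_order = {m: i for i, m in enumerate(sorted(truth.mirna_targets))}
    sites = []
    for mid, targets in sorted(truth.mirna_targets.items()):
        pos = 10 + 30 * mirna_order[mid]
        if pos + 7 > utr_length:
            raise ParameterError("utr_length too short for the staggered sites")
        for g in targets:
            sites.append((mid, g, pos))
    return UtrSimParams(
        utr_ids=genes,
        utr_length=utr_length,
        planted_sites=sites,
        mirna_ids=list(all_mirnas),
        seed=seed,
    )
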