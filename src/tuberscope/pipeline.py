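"""End-to-end orchestration: simulate -> DE -> cell type -> network -> miRNA -> report.

The demo path runs entirely on synthetic data.  A single declarative config
(YAML-compatible dict) carries all stage parameters and a global seed; a
rerun with the same config is byte-identical.  Each stage writes its outputs
before the next starts, and the final report restates only numbers that are
recomputable from those files.
"""

from __future__ import annotations

import copy
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, celltype, diffexpr, io, mirna, network, synthetic


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "tuberscope_out",
    "stages": {
        "de": True,
        "celltype": True,
        "network": True,
        "mirna": True,
    },
    "simulate": {
        "bulk": {},  # BulkSimParams overrides
        "modules": {
            "anti_pairs": [[0, 1, 0.5], [1, 2, 0.5]],
        },
        "cell_reference": {},
        "utr_length": 300,
    },
    "de": {"fc_cut": 1.5, "alpha": 0.05, "fpkm_filter": 1.0, "quantile": True},
    "celltype": {"hi": 10.0, "lo": 1.0},
    "network": {
        "top_k": 10000,
        "min_size": 100,
        "cut_height": 0.99,
        "r2_threshold": 0.80,
        "signed": False,
    },
    "mirna": {"alpha": 0.05, "adjust": False, "min_seed": 7, "direction": "negative"},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise PipelineError(f"config: unknown key {where!r}")
        if isinstance(base[key], dict) and path != "simulate":
            if not isinstance(val, dict):
                raise PipelineError(f"config: {where!r} must be a mapping")
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and/or an override dict onto the defaults.

    Unknown keys are rejected, so typos fail loudly rather than silently
    falling back to a default.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _provenance_header(cfg: dict, stage: str) -> str:
    return f"# tuberscope {__version__} | stage={stage} | seed={cfg['seed']}\n"


def _write_table(df: pd.DataFrame, path: Path, cfg: dict, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg, stage))
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_stage_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a stage output TSV, skipping the provenance comment line."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def run_pipeline(cfg: dict, log=None) -> dict:
    """Run all enabled stages on synthetic data; returns the run report."""

    def say(stage: str, msg: str) -> None:
        if log is not None:
            log(f"[{stage}] {msg}")

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: cfg[k] for k in ("de", "celltype", "network", "mirna")},
        "stages": {},
    }

    # ---- simulate ---------------------------------------------------------
    try:
        bulk_params = synthetic.BulkSimParams(seed=seed, **cfg["simulate"]["bulk"])
        counts, ann, meta, bulk_truth = synthetic.simulate_bulk(bulk_params)
        mod_over = dict(cfg["simulate"]["modules"])
        anti = [tuple(t) for t in mod_over.pop("anti_pairs", [])]
        mod_params = synthetic.ModuleSimParams(
            seed=seed + 1, anti_pairs=anti, **mod_over
        )
        expr, mirna_expr, mod_truth = synthetic.simulate_modules(mod_params)
        ref_params = synthetic.CellRefSimParams(
            seed=seed + 2, **cfg["simulate"]["cell_reference"]
        )
        ref_counts, ref_labels, ref_truth = synthetic.simulate_cell_reference(ref_params)
        utr_params = synthetic.utr_params_from_module_truth(
            mod_truth,
            all_mirnas=mirna_expr.gene_ids,
            utr_length=int(cfg["simulate"]["utr_length"]),
            seed=seed + 3,
        )
        utr_seqs, mirna_seqs, utr_truth = synthetic.simulate_utrs(utr_params)

        io.write_expression(counts, outdir / "bulk_counts.tsv")
        io.write_annotation(ann, outdir / "bulk_annotation.tsv")
        io.write_metadata(meta, outdir / "bulk_metadata.tsv")
        io.write_expression(expr, outdir / "module_expression.tsv")
        io.write_expression(mirna_expr, outdir / "mirna_expression.tsv")
        io.write_expression(ref_counts, outdir / "reference_counts.tsv")
        ref_labels.to_frame().rename_axis("sample_id").to_csv(
            outdir / "reference_labels.tsv", sep="\t", lineterminator="\n"
        )
        io.write_fasta(utr_seqs, outdir / "utrs.fa")
        io.write_fasta(mirna_seqs, outdir / "mirnas.fa")
        truth = synthetic.SyntheticTruth(
            de_genes=bulk_truth.de_genes,
            module_of=mod_truth.module_of,
            anti_pairs=mod_truth.anti_pairs,
            mirna_targets=mod_truth.mirna_targets,
            specific_genes=ref_truth.specific_genes,
            planted_sites=utr_truth.planted_sites,
        )
        io.write_json(truth.to_json_dict(), outdir / "truth.json")
        report["stages"]["simulate"] = {
            "n_bulk_genes": counts.shape[0],
            "n_bulk_samples": counts.shape[1],
            "n_planted_de": len(truth.de_genes),
            "n_module_genes": expr.shape[0],
            "n_mirna": mirna_expr.shape[0],
            "n_reference_genes": ref_counts.shape[0],
            "n_planted_specific": len(truth.specific_genes),
            "n_planted_sites": len(truth.planted_sites),
        }
        say("simulate", f"planted {len(truth.de_genes)} DE genes, "
            f"{len(truth.planted_sites)} UTR sites")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"simulate: {e}") from e

    # ---- differential expression -----------------------------------------
    de_table = None
    if cfg["stages"]["de"]:
        try:
            opts = diffexpr.DEOptions(
                fc_cut=cfg["de"]["fc_cut"],
                alpha=cfg["de"]["alpha"],
                fpkm_filter=cfg["de"]["fpkm_filter"],
                quantile=cfg["de"]["quantile"],
            )
            de_table = diffexpr.run_de_mrna(counts, ann, meta, opts)
            _write_table(de_table, outdir / "de_mrna.tsv", cfg, "de")
            status = de_table["status"].value_counts()
            report["stages"]["de"] = {
                "n_tested": int((de_table["status"] != "filtered").sum()),
                "n_filtered": int(status.get("filtered", 0)),
                "n_over": int(status.get("over", 0)),
                "n_under": int(status.get("under", 0)),
            }
            say("de", f"{report['stages']['de']['n_over']} over, "
                f"{report['stages']['de']['n_under']} under")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"de: {e}") from e

    # ---- cell-type specificity -------------------------------------------
    if cfg["stages"]["celltype"]:
        try:
            calls = celltype.call_specific_genes(
                ref_counts, ref_labels, hi=cfg["celltype"]["hi"], lo=cfg["celltype"]["lo"]
            )
            _write_table(calls, outdir / "celltype_calls.tsv", cfg, "celltype")
            n_calls = calls["cell_type"].notna().sum()
            section = {"n_specific_calls": int(n_calls)}
            if de_table is not None:
                enr = pd.concat(
                    [
                        celltype.enrichment_by_class(de_table, calls, d)
                        for d in ("over", "under")
                    ],
                    ignore_index=True,
                )
                _write_table(
                    enr.set_index("cell_type"),
                    outdir / "celltype_enrichment.tsv",
                    cfg,
                    "celltype",
                )
                section["n_enrichment_tests"] = int(len(enr))
            report["stages"]["celltype"] = section
            say("celltype", f"{n_calls} specific genes called")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"celltype: {e}") from e

    # ---- co-expression network -------------------------------------------
    mset = None
    if cfg["stages"]["network"]:
        try:
            ncfg = cfg["network"]
            mset, scan = network.build_network(
                expr,
                top_k=ncfg["top_k"],
                r2_threshold=ncfg["r2_threshold"],
                min_size=ncfg["min_size"],
                cut_height=ncfg["cut_height"],
                signed=ncfg["signed"],
            )
            _write_table(
                mset.labels.to_frame().rename_axis("gene_id"),
                outdir / "module_labels.tsv", cfg, "network",
            )
            _write_table(
                mset.eigengenes.rename_axis("module"),
                outdir / "module_eigengenes.tsv", cfg, "network",
            )
            _write_table(
                mset.kme.rename_axis("gene_id"), outdir / "module_kme.tsv", cfg, "network"
            )
            _write_table(
                scan.table, outdir / "soft_power_scan.tsv", cfg, "network"
            )
            sizes = {
                int(m): int((mset.labels == m).sum()) for m in mset.module_ids
            }
            report["stages"]["network"] = {
                "soft_power": scan.chosen,
                "scale_free_r2": float(scan.table.loc[scan.chosen, "r_squared"]),
                "n_modules": len(sizes),
                "module_sizes": sizes,
                "n_unassigned": int((mset.labels == 0).sum()),
            }
            say("network", f"beta={scan.chosen}, {len(sizes)} modules")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"network: {e}") from e

    # ---- miRNA integration ------------------------------------------------
    if cfg["stages"]["mirna"]:
        if mset is None:
            raise PipelineError("mirna: the network stage must run first")
        try:
            mcfg = cfg["mirna"]
            links = mirna.correlate_mirna_modules(
                mirna_expr, mset.eigengenes, alpha=mcfg["alpha"], adjust=mcfg["adjust"]
            )
            hits = mirna.predict_targets_seed_match(
                mirna_seqs, utr_seqs, min_seed=mcfg["min_seed"]
            )
            triples = mirna.intersect_targets_with_modules(
                links, hits, mset.labels, direction=mcfg["direction"]
            )
            _write_table(
                links.set_index("mirna_id"), outdir / "mirna_module_links.tsv", cfg, "mirna"
            )
            _write_table(
                mirna.predictions_table(hits).set_index("mirna_id"),
                outdir / "target_predictions.tsv", cfg, "mirna",
            )
            io.write_json(triples, outdir / "module_target_triples.json")
            report["stages"]["mirna"] = {
                "n_significant_links": int(links["significant"].sum()),
                "n_predicted_sites": len(hits),
                "n_triples": len(triples),
            }
            say("mirna", f"{len(triples)} module-target triples")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"mirna: {e}") from e

    write_report(report, outdir)
    return report


def recompute_report_numbers(outdir: str | Path) -> dict:
    """Recompute the report's headline numbers from the stage output files.

    Used for the self-consistency check: every count in ``report.json`` must
    be derivable from the TSV/JSON artifacts next to it.
    """
    outdir = Path(outdir)
    out: dict = {}
    de_path = outdir / "de_mrna.tsv"
    if de_path.exists():
        de = read_stage_table(de_path, index_col=0)
        out["de"] = {
            "n_tested": int((de["status"] != "filtered").sum()),
            "n_filtered": int((de["status"] == "filtered").sum()),
            "n_over": int((de["status"] == "over").sum()),
            "n_under": int((de["status"] == "under").sum()),
        }
    labels_path = outdir / "module_labels.tsv"
    if labels_path.exists():
        labels = read_stage_table(labels_path, index_col=0)["module"]
        sizes = labels[labels != 0].value_counts()
        out["network"] = {
            "n_modules": int(len(sizes)),
            "module_sizes": {int(k): int(v) for k, v in sizes.items()},
            "n_unassigned": int((labels == 0).sum()),
        }
    calls_path = outdir / "celltype_calls.tsv"
    if calls_path.exists():
        calls = read_stage_table(calls_path, index_col=0)
        out["celltype"] = {"n_specific_calls": int(calls["cell_type"].notna().sum())}
    links_path = outdir / "mirna_module_links.tsv"
    if links_path.exists():
        links = read_stage_table(links_path)
        out["mirna"] = {"n_significant_links": int(links["significant"].sum())}
    return out


def write_report(report: dict, outdir: str | Path) -> None:
    """Emit the run report as JSON plus a short human-readable text file."""
    outdir = Path(outdir)
    io.write_json(report, outdir / "report.json")
    lines = [
        f"tuberscope {report['version']} run report (seed {report['seed']})",
        "",
    ]
    for stage, section in report["stages"].items():
        lines.append(f"{stage}:")
        for key, val in section.items():
            lines.append(f"  {key}: {val}")
    absent = [
        s for s in ("de", "celltype", "network", "mirna")
        if s not in report["stages"]
    ]
    for s in absent:
        lines.append(f"{s}: absent (stage disabled)")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
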