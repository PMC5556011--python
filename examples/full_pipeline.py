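"""Run every stage end to end on synthetic data and print the run report.

Equivalent to `tuberscope run --seed 5 --outdir tuberscope_out`; all stage
outputs (TSV/FASTA/JSON) plus report.json/report.txt land in the output
directory, and a rerun with the same config is byte-identical.
"""

import json

from tuberscope import pipeline

cfg = pipeline.load_config(
    overrides={"seed": 5, "outdir": "tuberscope_out", "network": {"min_size": 50}}
)
report = pipeline.run_pipeline(cfg, log=print)

print(json.dumps(report["stages"], indent=2))
print("Per stage: input sizes, planted truth counts, DE calls by direction,")
print("module count/sizes and the number of significant miRNA-module links.")
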