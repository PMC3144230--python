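"""Run the full pipeline from one config: simulate a genome and read library,
characterize the family, map the reads, and compute the signature summary.

Equivalent shell command:
    tc1scope run --outdir out --seed 17
"""

import json

from tc1scope import run_pipeline

config = {
    "genome": {"genome_len": 200_000, "n_chrom": 1, "n_copies": 12, "n_intact": 4},
    "reads": {"n_reads": 1500, "n_background": 300},
}
report = run_pipeline(config, "out_pipeline", seed=17)

print(json.dumps({k: v for k, v in report.items() if k != "config"}, indent=2))
# report.json plus FASTA/FASTQ/TSV products are in out_pipeline/; counts
# reconcile at every filter (raw = preprocessed + dropped by reason).
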