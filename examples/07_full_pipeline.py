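"""Run every stage end to end from files, the way the CLI does.

Equivalent shell commands:
    txrefine simulate --seed 1 --out-dir scratch/demo/data
    txrefine run --data-dir scratch/demo/data --out-dir scratch/demo/out
"""

import tempfile

from txrefine.pipeline import run_from_dir
from txrefine.simulate import SimulationConfig, simulate

with tempfile.TemporaryDirectory() as tmp:
    data_dir = f"{tmp}/data"
    out_dir = f"{tmp}/out"
    simulate(SimulationConfig(seed=1)).write(data_dir)
    result = run_from_dir(data_dir, out_dir)

    for stage, counts in result.report.stage_counts.items():
        print(f"[{stage}]")
        for key, value in counts.items():
            print(f"  {key}: {value}")
    print("\noutputs: final.gtf, merge_report.tsv, effects.tsv, error_calls.tsv,")
    print("         rna_passing.vcf, rna_failing.vcf, report.json, support_table.tsv,")
    print("         error_matrix.tsv, venn.tsv")
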