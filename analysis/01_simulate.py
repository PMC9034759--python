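"""Generate the synthetic connectome export the rest of the analysis reads.

Writes synapse, edge and cell-type tables (plus the generative ground truth)
under results/run_seed1/ and reports the basic bookkeeping.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from lobtype.pipeline import run_stage


def main():
    rundir = run_stage(config(), RUN_DIR, "simulate")
    syn = pd.read_csv(rundir / "synapses.tsv", sep="\t", comment="#")
    gt = pd.read_csv(rundir / "ground_truth.tsv", sep="\t", comment="#")
    print(f"wrote {rundir}")
    print(f"  {len(syn)} synapses across {syn['cell_id'].nunique()} cells")
    print(f"  {len(gt)} ground-truth columnar cells over {gt['true_type'].nunique()} types")


if __name__ == "__main__":
    main()
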