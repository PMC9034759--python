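"""Extract per-cell features and assemble the clustering matrix.

Applies the inclusion filter (unlabeled, lobula-only, 51-499 total sites),
computes synapse spread, the 14-bin innervation-depth histogram (smoothed)
and the per-target-type connectivity counts, then normalizes each block by
its total dispersion and weights them 5/1/3.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from lobtype.pipeline import run_stage


def main():
    rundir = run_stage(config(), RUN_DIR, "features")
    fm = pd.read_csv(rundir / "features.tsv", sep="\t", comment="#")
    norm = json.loads((rundir / "normalization.json").read_text())
    print(f"feature matrix: {fm.shape[0]} cells of interest x {fm.shape[1] - 1} features")
    print("raw block dispersions (sum of variances):")
    for k, v in norm["total_dispersion"].items():
        print(f"  {k}: {v:.4g}")
    print(f"block weights {norm['block_weights']} applied after /sqrt(dispersion)")


if __name__ == "__main__":
    main()
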