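"""Quantify relative input from the clusters to the projection-neuron panel.

For each labeled target type, the synaptic input it receives from the cells
of interest is split across clusters (rows normalized to 1), minor
contributors (<5%) are lumped into "others", and the target types are
clustered by their input profiles.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from lobtype.pipeline import run_stage


def main():
    rundir = run_stage(config(), RUN_DIR, "project")
    rc = pd.read_csv(rundir / "relative_connectivity_lumped.tsv", sep="\t", comment="#",
                     index_col="target_type")
    print("relative input fractions (lumped at 5%):")
    for t, row in rc.iterrows():
        major = row[row > 0].sort_values(ascending=False)
        desc = ", ".join(f"cluster {c}: {v:.0%}" if c != "others" else f"others: {v:.0%}"
                         for c, v in major.items())
        print(f"  {t:<6} <- {desc}")
    print(f"target dendrogram written to {rundir / 'targets.nwk'}")


if __name__ == "__main__":
    main()
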