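"""Shared configuration for the analysis drivers.

One synthetic connectome (8 unlabeled columnar types x 60 cells over a
12-type labeled downstream panel, seed 1) analysed end to end; K is set to
the number of generated types, the value a typing study would choose when
the type count is known.
"""

from pathlib import Path

from lobtype.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run_seed1"


def config() -> RunConfig:
    return RunConfig(seed=1, K=8)
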