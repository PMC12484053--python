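"""Score a table of convolution layer shapes with FLOPs and weight counts.

A standalone utility step: writes results/complexity.csv for an example
stack of layers (a small detection-head-like progression).
"""

from pathlib import Path

import pandas as pd

from phenoseed.complexity import score_layers

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    layers = pd.DataFrame(
        {
            "H": [160, 80, 40, 20],
            "W": [160, 80, 40, 20],
            "K": [3, 3, 3, 1],
            "C_in": [16, 32, 64, 128],
            "C_out": [32, 64, 128, 128],
        }
    )
    scored = score_layers(layers)
    scored.to_csv(RESULTS / "complexity.csv", index=False)
    total_flops = scored.flops.sum()
    total_params = scored.params.sum()
    print(scored.to_string(index=False))
    print(f"totals: {total_flops/1e9:.2f} GFLOPs, {total_params/1e6:.3f} M params")


if __name__ == "__main__":
    main()
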