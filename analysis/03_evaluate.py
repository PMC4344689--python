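"""Fuzzy comprehensive evaluation of the four factors and the composite index.

Runs membership grading and weighted fuzzy composition per factor,
defuzzifies to the scalar hazard / exposure / vulnerability / restorability
indices, and combines them into the risk index. Writes the factor and index
rasters under results/evaluation/ and prints their ranges.
"""

from pathlib import Path

from deserisk import SyntheticConfig, run_pipeline
from deserisk.grid import write_ascii_grid

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results" / "evaluation"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(SyntheticConfig(seed=SEED))

    for factor, layer in result.factor_indices.items():
        write_ascii_grid(layer, OUT / f"factor_{factor}.asc")
        vals = layer.unmasked()
        print(f"{factor:>14} index: mean {vals.mean():.4f}, "
              f"range [{vals.min():.4f}, {vals.max():.4f}]")
    write_ascii_grid(result.ddri, OUT / "ddri.asc")
    vals = result.ddri.unmasked()
    print(f"\ncomposite risk index: mean {vals.mean():.4f}, "
          f"range [{vals.min():.4f}, {vals.max():.4f}]")
    w = result.model.factor_weights
    print("factor weights:", {k: round(v, 4) for k, v in w.items()})


if __name__ == "__main__":
    main()
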