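"""Derive indicator weights and check factor totals.

Reports the canonical combined weights per factor (whose sums are the four
factor weights used by the risk index), and contrasts them with purely
objective entropy weights computed from the synthetic layers. Writes
results/weights.csv.
"""

from pathlib import Path

import pandas as pd

from deserisk import SyntheticConfig, generate_indicator_layers
from deserisk.pipeline import factor_weight_vectors

SEED = 42
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=SEED)
    layers = generate_indicator_layers(config)

    table = factor_weight_vectors(config.indicators, mode="table")
    entropy = factor_weight_vectors(
        config.indicators, mode="entropy", layers=layers, seed=SEED
    )

    rows = []
    for factor in table:
        for name in table[factor].names:
            rows.append(
                {
                    "factor": factor,
                    "indicator": name,
                    "table_weight_within_factor": table[factor][name],
                    "entropy_weight_within_factor": entropy[factor][name],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "weights.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

    print("\nfactor weight totals (combined indicator weights):")
    for factor, total in config.indicators.factor_weights().items():
        print(f"  {factor:>14}: {total:.4f}")


if __name__ == "__main__":
    main()
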