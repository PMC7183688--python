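#!/usr/bin/env python
"""Knockdown-synergy demonstration on simulated qPCR time courses.

Simulates the four-condition knockdown design (reference, suppressor
reduction, enhancer augment, combined) for three cytokines over 0/4/8/12 h
with a synergy multiplier injected late for two genes (1.3 and 1.7 at 12 h)
and early for one (1.4 at 4 h), then recovers the ΔΔCt folds, ŝ per
timepoint, and Welch-t star annotations.

Writes results/synergy/synergy_table.tsv.
"""

import argparse
from pathlib import Path

from epikit.simulate import QpcrConfig, simulate_qpcr
from epikit.synergy import synergy_table

OUT = Path(__file__).resolve().parent.parent / "results" / "synergy"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=23)
    args = parser.parse_args()

    cfg = QpcrConfig(synergy={
        ("CCL2", 12.0): 1.3, ("CXCL8", 12.0): 1.7, ("IL6", 4.0): 1.4,
    })
    data = simulate_qpcr(cfg, args.seed)
    table = synergy_table(data)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "synergy_table.tsv", sep="\t", index=False, float_format="%.4g")
    active = table[table["timepoint_h"] > 0]
    print(active[["gene", "timepoint_h", "fold_reduction", "fold_augment",
                  "fold_combined", "s_hat", "stars_low_a20_high_ube"]]
          .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print("\nInjected synergies: CCL2 1.3 @ 12 h, CXCL8 1.7 @ 12 h, IL6 1.4 @ 4 h"
          f"\nFull table in {OUT}")


if __name__ == "__main__":
    main()
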