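#!/usr/bin/env python
"""Quantify repeat contraction (loop loss) from synthetic Sanger traces.

Mixes the looped-strand control read-out with the loop-free contraction
product at 75% loop loss, decomposes 10 replicate noisy traces, and reports
the total shortening signal (the paper-scale readout: the fraction of trace
signal showing DNA shortening).  Outputs under results/tracedecomp/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nickloop import tracedecomp
from nickloop.pipeline import (
    CONTRACTION_FRACTION,
    decompose_mixture,
    make_standard_substrate,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "tracedecomp"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    sub = make_standard_substrate()
    rows = []
    for r in range(10):
        result, summary, templates, mutant = decompose_mixture(
            sub, "contraction", CONTRACTION_FRACTION, 0.01, SEED + 200 + r)
        rows.append({
            "seed": SEED + 200 + r,
            "shortening_signal": summary["shortening_signal"],
            "shortening_signal_incl_residual": summary["shortening_signal_incl_residual"],
            "dominant_shift": summary["dominant_shift"],
            "r_squared": summary["r_squared"],
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "contraction_recovery.tsv", sep="\t", index=False)
    result.to_frame().to_csv(OUT / "contraction_components.tsv", sep="\t", index=False)
    tracedecomp.plot_decomposition(mutant, templates, result,
                                   OUT / "contraction_decomposition.svg")

    print(f"planted loop-loss fraction: {CONTRACTION_FRACTION:.2f}")
    print(f"mean shortening signal: {df['shortening_signal'].mean():.4f} "
          f"(all dominant shifts = {sorted(df['dominant_shift'].unique())})")
    print(f"shortening signal >= 0.70 in {int((df['shortening_signal'] >= 0.70).sum())}"
          f"/10 replicates")
    print(f"tables and plot in {OUT}")


if __name__ == "__main__":
    main()
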