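#!/usr/bin/env python
"""Expected loss-of-silencing rates from random tetramer segregation.

If one inherited parental H3-H4 tetramer suffices to propagate the
silenced state, the expected loss rate per daughter chromatid is 0.5**N
for an N-nucleosome domain.  This script tabulates that prediction for
the CRASH locus alleles (N14 down to N7) and the FLAME locus alleles
(sN12 down to sN6), plus the stricter two-tetramer-threshold variant.

Writes results/predicted_loss_rates.tsv.
"""

from pathlib import Path

import pandas as pd

from episwitch.segregation import SegregationModel, loss_probability, predicted_rate_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    crash = predicted_rate_table([SegregationModel(n) for n in range(7, 15)])
    crash.insert(0, "locus", "HMRalpha::cre")
    flame = predicted_rate_table([SegregationModel(n) for n in range(6, 13)])
    flame.insert(0, "locus", "HMRalpha::GFP")
    strict = predicted_rate_table([SegregationModel(n, min_parental_required=2) for n in range(7, 15)])
    strict.insert(0, "locus", "HMRalpha::cre (m=2)")

    table = pd.concat([crash, flame, strict], ignore_index=True)
    out = RESULTS / "predicted_loss_rates.tsv"
    table.to_csv(out, sep="\t", index=False)

    n14 = 100 * loss_probability(SegregationModel(14))
    n7 = 100 * loss_probability(SegregationModel(7))
    print(f"full-length locus (N14): expected loss in {n14:.4f}% of divisions (~0.006%)")
    print(f"smallest allele (N7):    expected loss in {n7:.4f}% of divisions (~1%)")
    print(f"ratio N7/N14: {n7 / n14:.0f}x — the model predicts far less stable short domains")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
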