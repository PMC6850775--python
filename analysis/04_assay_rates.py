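#!/usr/bin/env python
"""Quantify the flow-cytometry and pedigree assays on the synthetic data.

- CRASH: apparent silencing-loss rate (RFP+GFP+ among RFP+ cells) on the
  simulated wild-type colony, compared with the generator's closed-form
  expectation 1-(1-q)^persistence.
- Pedigrees: per-generation loss and establishment rates with Wilson 95%
  confidence intervals, and Yates chi-square pairwise comparisons of the
  loss rates across genotypes.

Reads results/synthetic/ (run 02 first); writes results/assay_rates.json.
"""

import json
from pathlib import Path

from episwitch import io as eio
from episwitch.assays import compare_rates_yates, crash_apparent_loss_rate, pedigree_rate

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pop = eio.read_flow_events(RESULTS / "synthetic" / "crash_events.csv")
    crash = crash_apparent_loss_rate(pop)
    expected = 1 - (1 - 0.001) ** 2
    print(f"CRASH apparent loss rate: {crash.rate:.5f} "
          f"(closed-form expectation {expected:.5f}; {crash.n_rfp_gfp} double-positive "
          f"of {crash.n_rfp_gfp + crash.n_rfp_only} RFP+ cells)")

    counts = eio.read_pedigree(RESULTS / "synthetic" / "pedigree.tsv")
    rate_rows = []
    for c in counts:
        rate, (lo, hi) = pedigree_rate(c)
        rate_rows.append({"genotype": c.genotype, "direction": c.direction,
                          "n_events": c.n_events, "n_divisions": c.n_divisions,
                          "rate": rate, "ci95": [lo, hi]})
        print(f"  {c.genotype:>14} {c.direction:>13}: {rate:.4f} "
              f"[{lo:.4f}, {hi:.4f}] ({c.n_events}/{c.n_divisions})")

    loss_counts = [c for c in counts if c.direction == "loss"]
    comparisons = []
    for i in range(len(loss_counts)):
        for j in range(i + 1, len(loss_counts)):
            chi2, p = compare_rates_yates(loss_counts[i], loss_counts[j])
            comparisons.append({"a": loss_counts[i].genotype, "b": loss_counts[j].genotype,
                                "chi2": chi2, "p": p})
            flag = "*" if p < 0.05 else " "
            print(f"  Yates {loss_counts[i].genotype} vs {loss_counts[j].genotype}: "
                  f"chi2={chi2:.2f} p={p:.3f}{flag}")

    out = RESULTS / "assay_rates.json"
    out.write_text(json.dumps({
        "crash": {"apparent_loss_rate": crash.rate, "expected": expected,
                  "n_rfp_gfp": crash.n_rfp_gfp, "n_rfp_only": crash.n_rfp_only,
                  "n_gfp_only": crash.n_gfp_only},
        "pedigree_rates": rate_rows,
        "yates_loss_comparisons": comparisons,
    }, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
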