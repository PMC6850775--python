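#!/usr/bin/env python
"""Generate the synthetic inputs every downstream stage consumes.

Produces, under results/synthetic/:

- crash_events.csv      — CRASH flow events for a wild-type-like colony
                          (loss 0.1%/division, RFP persisting 2 generations)
- relaxation.tsv        — sorted-population time courses for the four
                          replisome genotypes, both sort directions,
                          at their per-generation rate pairs
- pedigree.tsv          — time-lapse division counts per genotype
- mnase_full.bed        — fragments for a 14-nucleosome locus
- mnase_deletion.bed    — same locus with one dyad pair deleted
"""

from pathlib import Path

from episwitch import io as eio
from episwitch._util import config_hash
from episwitch.assays import PedigreeCounts
from episwitch.kinetics import PER_GENERATION, TwoStateRates
from episwitch.simulate import (
    LineageSimConfig,
    MNaseSimConfig,
    RelaxationSimConfig,
    simulate_crash_population,
    simulate_mnase_fragments,
    simulate_pedigree,
    simulate_relaxation,
)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

# per-generation (k_on, k_off) for the four replisome genotypes
GENOTYPE_RATES = {
    "wild_type": (0.003, 0.11),
    "dpb3": (0.014, 0.78),
    "mcm2_3A": (0.018, 0.17),
    "dpb3_mcm2_3A": (0.033, 0.5),
}

MNASE_REGION = ("chrIII", 292_000, 295_000)
MNASE_DYADS = tuple(292_300 + 165 * i for i in range(14))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    crash_cfg = LineageSimConfig(loss_rate=0.001, rfp_persistence_gens=2,
                                 n_founders=16, n_generations=13, seed=SEED)
    pop = simulate_crash_population(crash_cfg)
    eio.write_flow_events(pop, OUT / "crash_events.csv",
                          provenance={"config_hash": config_hash(crash_cfg), "seed": SEED})
    print(f"crash_events.csv: {len(pop)} cells")

    courses = []
    for i, (geno, (k_on, k_off)) in enumerate(sorted(GENOTYPE_RATES.items())):
        rates = TwoStateRates(k_on, k_off, PER_GENERATION)
        for j, state in enumerate(("sorted_silenced", "sorted_expressed")):
            cfg = RelaxationSimConfig(rates=rates, initial_state=state, genotype=geno,
                                      seed=SEED + 10 * i + j)
            courses.extend(simulate_relaxation(cfg))
    eio.write_timecourses(courses, OUT / "relaxation.tsv", provenance={"seed": SEED})
    print(f"relaxation.tsv: {len(courses)} time courses "
          f"({len(GENOTYPE_RATES)} genotypes x 2 sorts x 3 technical replicates)")

    counts: list[PedigreeCounts] = []
    for i, (geno, (k_on, k_off)) in enumerate(sorted(GENOTYPE_RATES.items())):
        rates = TwoStateRates(k_on, k_off, PER_GENERATION)
        loss, est = simulate_pedigree(rates, n_divisions=1000, seed=SEED + i,
                                      n_divisions_establishment=120)
        counts.append(PedigreeCounts(geno, loss.direction, loss.n_divisions, loss.n_events))
        counts.append(PedigreeCounts(geno, est.direction, est.n_divisions, est.n_events))
    eio.write_pedigree(counts, OUT / "pedigree.tsv", provenance={"seed": SEED})
    print(f"pedigree.tsv: {len(counts)} genotype/direction rows")

    full = MNaseSimConfig(region=MNASE_REGION, dyads=MNASE_DYADS, coverage=150, seed=SEED)
    eio.write_bed3(simulate_mnase_fragments(full), OUT / "mnase_full.bed",
                   provenance={"config_hash": config_hash(full), "seed": SEED})
    deletion_dyads = MNASE_DYADS[:4] + MNASE_DYADS[6:]  # drop dyads 5-6
    deletion = MNaseSimConfig(region=MNASE_REGION, dyads=deletion_dyads, coverage=150, seed=SEED)
    eio.write_bed3(simulate_mnase_fragments(deletion), OUT / "mnase_deletion.bed",
                   provenance={"config_hash": config_hash(deletion), "seed": SEED})
    print(f"mnase_full.bed / mnase_deletion.bed: {len(MNASE_DYADS)} vs {len(deletion_dyads)} dyads")


if __name__ == "__main__":
    main()
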