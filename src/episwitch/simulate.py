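"""Seed-reproducible generators for every input class of the pipeline.

The generators emulate the four measurement types of the study design:

- CRASH flow populations: colonies grown from silenced founders in which
  each cell, per division, loses silencing with a fixed probability and
  thereafter irreversibly expresses GFP, retaining RFP for a fixed
  number of generations before dilution (wild type loses silencing in
  ~0.1% of divisions; RFP persists ~2 generations by default).
- FACS relaxation time courses: sorted pure populations whose latent
  expressed fraction follows the two-state closed form, observed through
  binomial sampling of >= 500 cells per time point across 3 technical
  replicates with slightly staggered sampling times.
- Pedigree counts: Bernoulli switching per observed division conditioned
  on the parent's state, as scored by time-lapse microscopy.
- MNase fragment sets: mononucleosomal fragments (lengths ~N(147, sd))
  centered on jittered dyad positions.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from episwitch._util import config_hash
from episwitch.assays import FlowPopulation, PedigreeCounts, LOSS, ESTABLISHMENT
from episwitch.kinetics import (
    DEFAULT_GENERATION_TIME_HR,
    PER_GENERATION,
    RelaxationTimeCourse,
    TwoStateRates,
    to_per_hour,
    x_on_predicted,
)
from episwitch.mnase import FragmentSet

__all__ = [
    "LineageSimConfig",
    "RelaxationSimConfig",
    "MNaseSimConfig",
    "simulate_crash_population",
    "simulate_relaxation",
    "simulate_pedigree",
    "simulate_state_lineages",
    "simulate_mnase_fragments",
    "DEFAULT_TIME_POINTS_HR",
    "DEFAULT_STAGGER_HR",
]

#: Base sampling grid for relaxation experiments, hours after sorting.
DEFAULT_TIME_POINTS_HR = (0.0, 4.0, 8.0, 12.0, 18.0, 24.0, 36.0, 48.0)
#: Offset between successive technical replicates' sampling times
#: (sorting took ~20 min per sample, staggering the clocks).
DEFAULT_STAGGER_HR = 1.0 / 3.0


@dataclass(frozen=True)
class LineageSimConfig:
    """CRASH colony growth: irreversible loss with transient RFP retention."""

    loss_rate: float = 0.001          # per division; wild-type CRASH ~0.1%
    establishment_rate: float = 0.0   # ignored by CRASH (reporter is irreversible)
    n_generations: int = 12
    n_founders: int = 4
    initial_state: str = "silenced"
    rfp_persistence_gens: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "establishment_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rfp_persistence_gens < 0:
            raise ValueError("rfp_persistence_gens must be >= 0")
        if self.n_generations < 1 or self.n_founders < 1:
            raise ValueError("n_generations and n_founders must be >= 1")


@dataclass(frozen=True)
class RelaxationSimConfig:
    """Sorted-population relaxation experiment design."""

    rates: TwoStateRates                      # per-generation rates
    generation_time_hr: float = DEFAULT_GENERATION_TIME_HR
    time_points_hr: tuple[float, ...] = DEFAULT_TIME_POINTS_HR
    stagger_hr: float = DEFAULT_STAGGER_HR
    n_cells_sampled: int = 500                # paper: n > 500 cells per sample
    n_technical_replicates: int = 3
    initial_state: str = "sorted_silenced"
    genotype: str = "synthetic"
    latent: str = "closed_form"               # or "agent" (per-cell Markov chain)
    n_agents: int = 5000                      # agent-based latent population size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rates.unit != PER_GENERATION:
            raise ValueError("RelaxationSimConfig.rates must be per generation")
        if self.n_cells_sampled < 1:
            raise ValueError("n_cells_sampled must be >= 1")
        if self.latent not in ("closed_form", "agent"):
            raise ValueError(f"latent must be 'closed_form' or 'agent', got {self.latent!r}")


@dataclass(frozen=True)
class MNaseSimConfig:
    """Synthetic mononucleosomal fragments around known dyads."""

    region: tuple[str, int, int]
    dyads: tuple[int, ...]
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 8.0
    midpoint_jitter_sd: float = 10.0
    coverage: int = 50                        # fragments per dyad
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        _, start, end = self.region
        for d in self.dyads:
            if not (start <= d < end):
                raise ValueError(f"dyad {d} outside region {self.region}")


# ---------------------------------------------------------------------------
# CRASH

def simulate_crash_population(cfg: LineageSimConfig) -> FlowPopulation:
    """Grow a CRASH colony and emit boolean-dialect flow events.

    State machine per cell: RFP+ GFP- (silenced) → on loss → RFP+ GFP+
    for ``rfp_persistence_gens`` generations → RFP- GFP+, irreversibly.
    The expected apparent loss rate (RFP+GFP+ among RFP+) is
    ``1 - (1 - loss_rate)**rfp_persistence_gens``.
    """
    if cfg.initial_state != "silenced":
        raise ValueError("CRASH founders must start silenced")
    rng = np.random.default_rng(cfg.seed)
    # state 0 = silenced; k >= 1 = generations since the loss event
    states = np.zeros(cfg.n_founders, dtype=np.int64)
    for _ in range(cfg.n_generations):
        states = np.repeat(states, 2)
        lost = states > 0
        states[lost] += 1
        silenced = ~lost
        new_loss = rng.random(silenced.sum()) < cfg.loss_rate
        idx = np.flatnonzero(silenced)[new_loss]
        states[idx] = 1
    rfp_pos = states <= cfg.rfp_persistence_gens
    gfp_pos = states > 0
    events = pd.DataFrame({"rfp_pos": rfp_pos, "gfp_pos": gfp_pos})
    events.attrs["config_hash"] = config_hash(cfg)
    return FlowPopulation(events=events, genotype="crash_sim", replicate_id=str(cfg.seed))


# ---------------------------------------------------------------------------
# Relaxation time courses

def _latent_x_on_agent(cfg: RelaxationSimConfig, times_hr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent expressed fraction from a per-cell discrete-generation Markov chain."""
    k_on, k_off = cfg.rates.k_on, cfg.rates.k_off
    expressed = np.full(cfg.n_agents, cfg.initial_state == "sorted_expressed")
    gens = np.floor(times_hr / cfg.generation_time_hr).astype(int)
    out = np.empty_like(times_hr)
    g_done = 0
    order = np.argsort(gens)
    for i in order:
        while g_done < gens[i]:
            u = rng.random(cfg.n_agents)
            flip_on = (~expressed) & (u < k_on)
            flip_off = expressed & (u < k_off)
            expressed = expressed ^ flip_on ^ flip_off
            g_done += 1
        out[i] = expressed.mean()
    return out


def simulate_relaxation(cfg: RelaxationSimConfig) -> list[RelaxationTimeCourse]:
    """Simulate sorted-population relaxation observed by flow cytometry.

    The latent expressed fraction follows either the exact two-state
    closed form (default; per-hour rates are the per-generation rates
    divided by the generation time) or an agent-based per-cell Markov
    chain.  Observed counts are ``Binomial(n_cells_sampled, x_on(t))``.
    Technical replicates share the design but have staggered sampling
    times (the t=0 sort itself is not staggered).
    """
    rng = np.random.default_rng(cfg.seed)
    hourly = to_per_hour(cfg.rates)
    courses = []
    for r in range(cfg.n_technical_replicates):
        base = np.asarray(cfg.time_points_hr, dtype=float)
        times = base.copy()
        times[times > 0] += r * cfg.stagger_hr
        if cfg.latent == "closed_form":
            x = np.atleast_1d(x_on_predicted(hourly, times, cfg.initial_state))
        else:
            x = _latent_x_on_agent(cfg, times, rng)
        n_pos = rng.binomial(cfg.n_cells_sampled, np.clip(x, 0.0, 1.0))
        points = tuple((t, cfg.n_cells_sampled, int(k)) for t, k in zip(times, n_pos))
        courses.append(
            RelaxationTimeCourse(
                genotype=cfg.genotype,
                replicate_id=f"rep{r + 1}",
                initial_state=cfg.initial_state,
                points=points,
            )
        )
    return courses


# ---------------------------------------------------------------------------
# Pedigrees and state lineages

def simulate_pedigree(
    rates: TwoStateRates,
    n_divisions: int,
    seed: int,
    n_divisions_establishment: int | None = None,
) -> tuple[PedigreeCounts, PedigreeCounts]:
    """Bernoulli switching per observed division, conditioned on parent state.

    Divisions of silenced parents yield loss events at ``k_on`` per
    generation; divisions of expressed parents yield establishment
    events at ``k_off``.  Establishment observations may use a smaller
    division count (expressed cells are rare in these populations).
    """
    if rates.unit != PER_GENERATION:
        raise ValueError("simulate_pedigree expects per-generation rates")
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    n_est = n_divisions if n_divisions_establishment is None else n_divisions_establishment
    rng = np.random.default_rng(seed)
    n_loss = int(rng.binomial(n_divisions, rates.k_on))
    n_gain = int(rng.binomial(n_est, rates.k_off))
    return (
        PedigreeCounts(genotype="sim", direction=LOSS, n_divisions=n_divisions, n_events=n_loss),
        PedigreeCounts(genotype="sim", direction=ESTABLISHMENT, n_divisions=n_est, n_events=n_gain),
    )


def simulate_state_lineages(
    rates: TwoStateRates,
    n_cells: int,
    n_generations: int,
    seed: int,
    initial_state: str = "stationary",
) -> FlowPopulation:
    """Per-cell two-state Markov chain; emits a FLAME-style boolean population.

    ``initial_state`` is ``"silenced"``, ``"expressed"`` or
    ``"stationary"`` (each cell drawn from the stationary distribution
    ``k_on/(k_on+k_off)`` expressed).  The long-run expressed fraction
    converges to that stationary value regardless of the start.
    """
    if rates.unit != PER_GENERATION:
        raise ValueError("simulate_state_lineages expects per-generation rates")
    rng = np.random.default_rng(seed)
    if initial_state == "silenced":
        expressed = np.zeros(n_cells, dtype=bool)
    elif initial_state == "expressed":
        expressed = np.ones(n_cells, dtype=bool)
    elif initial_state == "stationary":
        expressed = rng.random(n_cells) < rates.equilibrium_expressed
    else:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    for _ in range(n_generations):
        u = rng.random(n_cells)
        flip_on = (~expressed) & (u < rates.k_on)
        flip_off = expressed & (u < rates.k_off)
        expressed = expressed ^ flip_on ^ flip_off
    events = pd.DataFrame({"rfp_pos": ~expressed, "gfp_pos": expressed})
    return FlowPopulation(events=events, genotype="flame_sim", replicate_id=str(seed))


# ---------------------------------------------------------------------------
# MNase fragments

def simulate_mnase_fragments(cfg: MNaseSimConfig) -> FragmentSet:
    """Mononucleosomal fragments centered on jittered dyad positions.

    Each dyad receives ``coverage`` fragments whose midpoints are
    ``dyad + N(0, midpoint_jitter_sd)`` (rounded) and whose lengths are
    ``N(fragment_length_mean, fragment_length_sd)`` truncated positive.
    """
    chrom, _, _ = cfg.region
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for dyad in cfg.dyads:
        mids = np.rint(dyad + rng.normal(0.0, cfg.midpoint_jitter_sd, cfg.coverage)).astype(int)
        lengths = np.rint(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, cfg.coverage)).astype(int)
        lengths = np.maximum(lengths, 1)
        starts = mids - lengths // 2
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lengths}))
    frags = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["chrom", "start", "end"])
    frags.attrs["config_hash"] = config_hash(cfg)
    return FragmentSet(fragments=frags, region=cfg.region)
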