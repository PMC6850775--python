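"""Binomial model of parental H3-H4 tetramer segregation.

During DNA replication each parental H3-H4 tetramer within a chromatin
domain is inherited intact by one of the two daughter chromatids.  Under
unbiased random segregation each tetramer lands on a given chromatid with
probability 1/2, independently of the others.  If propagating a silenced
state requires a daughter chromatid to inherit at least ``m`` parental
tetramers, the chance that a designated chromatid falls short — and the
silenced state is lost — is the lower binomial tail ``P(X < m)`` with
``X ~ Binomial(N, p)``, where ``N`` is the number of nucleosomes in the
domain and ``p`` the per-tetramer probability of segregating to that
chromatid.  With ``m = 1`` and ``p = 0.5`` this is the familiar
``0.5**N``: a three-nucleosome domain loses its state in one of eight
divisions, a fourteen-nucleosome domain in about 0.006% of divisions.

Replisome mutants that bias inheritance toward the leading or lagging
strand are modelled by moving ``p`` away from 0.5; the deprived chromatid
then sees per-tetramer probability ``1 - p``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationModel",
    "loss_probability",
    "per_division_loss_probability",
    "predicted_rate_table",
    "simulate_divisions",
]


@dataclass(frozen=True)
class SegregationModel:
    """Parameters of a tetramer-segregation scenario for one domain.

    Parameters
    ----------
    n_nucleosomes:
        Number of nucleosomes (hence parental tetramers available) in the
        silenced domain.  The *HMRα::cre* alleles span N7–N14 and the
        *HMRα::GFP* alleles sN6–sN12.
    min_parental_required:
        Minimum number of parental tetramers a daughter chromatid must
        inherit to keep the silenced state (``m``; default 1).
    p_strand:
        Probability that any one parental tetramer segregates to the
        designated daughter strand.  0.5 models unbiased random
        segregation; other values model strand-biased inheritance.
    """

    n_nucleosomes: int
    min_parental_required: int = 1
    p_strand: float = 0.5

    def __post_init__(self) -> None:
        if not (isinstance(self.n_nucleosomes, (int, np.integer)) and self.n_nucleosomes >= 1):
            raise ValueError(f"n_nucleosomes must be a positive integer, got {self.n_nucleosomes!r}")
        if not (isinstance(self.min_parental_required, (int, np.integer)) and self.min_parental_required >= 1):
            raise ValueError(
                f"min_parental_required must be a positive integer, got {self.min_parental_required!r}"
            )
        if self.min_parental_required > self.n_nucleosomes:
            raise ValueError(
                "min_parental_required must not exceed n_nucleosomes "
                f"(got min_parental_required={self.min_parental_required}, n_nucleosomes={self.n_nucleosomes})"
            )
        if not (0.0 <= self.p_strand <= 1.0):
            raise ValueError(f"p_strand must lie in [0, 1], got {self.p_strand!r}")


def _focal_probability(model: SegregationModel, focal: str) -> float:
    if focal == "designated":
        return model.p_strand
    if focal == "other":
        return 1.0 - model.p_strand
    raise ValueError(f"focal must be 'designated' or 'other', got {focal!r}")


def loss_probability(model: SegregationModel, focal: str = "designated") -> float:
    """Probability per division that one daughter chromatid loses the state.

    Returns the closed-form lower binomial tail ``P(X < m)`` for
    ``X ~ Binomial(n_nucleosomes, p)``, where ``p`` is the per-tetramer
    probability of segregating to the focal chromatid (``p_strand`` for
    the designated strand, ``1 - p_strand`` for its sister).

    With ``m=1, p=0.5`` this equals ``0.5**N`` — the probability of
    inheriting zero parental tetramers.
    """
    p = _focal_probability(model, focal)
    return float(stats.binom.cdf(model.min_parental_required - 1, model.n_nucleosomes, p))


def per_division_loss_probability(model: SegregationModel) -> float:
    """Probability that at least one of the two daughters loses the state.

    The loss counted by :func:`loss_probability` is per daughter
    chromatid; a division produces two daughters that split the ``N``
    tetramers between them (the designated strand receives ``X``, its
    sister ``N - X``), so a division yields at least one loss event with
    probability ``P(X < m or N - X < m)``.  For ``m = 1, p = 0.5`` this
    is ``2 * 0.5**N`` (the two tails are disjoint whenever ``2m <= N``).
    """
    n, m, p = model.n_nucleosomes, model.min_parental_required, model.p_strand
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p)
    either = (k < m) | (n - k < m)
    return float(pmf[either].sum())


def predicted_rate_table(models: list[SegregationModel]) -> pd.DataFrame:
    """Expected loss-of-silencing rates for a series of domain sizes.

    Returns one row per model with columns ``n_nucleosomes``,
    ``min_parental``, ``p_strand``, ``loss_prob`` and ``loss_pct``,
    sorted by ``n_nucleosomes`` descending (matching the N14→N7 strain
    series).
    """
    if not models:
        raise ValueError("predicted_rate_table requires a non-empty list of models")
    rows = [
        {
            "n_nucleosomes": m.n_nucleosomes,
            "min_parental": m.min_parental_required,
            "p_strand": m.p_strand,
            "loss_prob": loss_probability(m),
        }
        for m in models
    ]
    table = pd.DataFrame(rows)
    table["loss_pct"] = 100.0 * table["loss_prob"]
    return table.sort_values("n_nucleosomes", ascending=False, kind="stable").reset_index(drop=True)


def simulate_divisions(
    model: SegregationModel,
    n_divisions: int,
    seed: int,
    focal: str = "designated",
) -> tuple[float, np.ndarray]:
    """Monte-Carlo check of the closed-form loss probability.

    Each division draws ``n_nucleosomes`` independent Bernoulli
    segregation outcomes; a loss event is recorded when the focal
    chromatid receives fewer than ``min_parental_required`` parental
    tetramers.

    Returns
    -------
    (loss_fraction, inherited_counts):
        The empirical loss fraction and the per-division number of
        parental tetramers inherited by the focal chromatid.
    """
    if not (isinstance(n_divisions, (int, np.integer)) and n_divisions >= 1):
        raise ValueError(f"n_divisions must be a positive integer, got {n_divisions!r}")
    p = _focal_probability(model, focal)
    rng = np.random.default_rng(seed)
    # Sum of N Bernoulli(p) draws per division.
    counts = rng.binomial(model.n_nucleosomes, p, size=n_divisions)
    losses = counts < model.min_parental_required
    return float(losses.mean()), counts
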