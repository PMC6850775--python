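"""Silencing-loss and establishment rates from flow and pedigree data.

Two single-cell reporter assays are quantified here:

- CRASH (Cre-Reported Altered States of Heterochromatin): a transient
  loss of silencing at *HMRα::cre* excises RFP and switches the cell
  permanently to GFP.  Cells that lost silencing recently are RFP+ GFP+
  (RFP not yet diluted); the apparent loss rate is the fraction of
  still-RFP+ cells that are also GFP+.
- FLAME (FLuorescent Analysis of Metastable Expression): in ``sir1∆``,
  a GFP reporter at *HMR* reads out which heritable state (silenced or
  expressed) each cell occupies; population fractions give the
  equilibrium of the two-state switching process.

Pedigree counts from time-lapse microscopy (events per observed
division) are summarized as per-generation rates with Wilson score 95%
confidence intervals and compared between genotypes with the Yates
continuity-corrected chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FlowPopulation",
    "PedigreeCounts",
    "CrashRate",
    "FlameFractions",
    "crash_apparent_loss_rate",
    "crash_rate_summary",
    "flame_equilibrium_fractions",
    "gfp_gate_from_controls",
    "pedigree_rate",
    "compare_rates_yates",
    "GateSeparationWarning",
]

LOSS = "loss"
ESTABLISHMENT = "establishment"


class GateSeparationWarning(UserWarning):
    """Raised when too many events fall between the silenced and expressed gates."""


@dataclass
class FlowPopulation:
    """Per-cell two-channel flow events for one sample.

    ``events`` is a DataFrame in one of two dialects:

    - raw intensities: columns ``rfp``, ``gfp`` (arbitrary fluorescence
      units, >= 0), gated by ``rfp_threshold`` / ``gfp_threshold``;
    - pre-thresholded booleans: columns ``rfp_pos``, ``gfp_pos``.
    """

    events: pd.DataFrame
    genotype: str = ""
    replicate_id: str = ""
    rfp_threshold: float | None = None
    gfp_threshold: float | None = None

    def __post_init__(self) -> None:
        cols = set(self.events.columns)
        if {"rfp_pos", "gfp_pos"} <= cols:
            self._dialect = "boolean"
        elif {"rfp", "gfp"} <= cols:
            self._dialect = "raw"
            if (self.events[["rfp", "gfp"]] < 0).any().any():
                raise ValueError("fluorescence intensities must be >= 0")
        else:
            raise ValueError(
                "events must have columns rfp/gfp (raw) or rfp_pos/gfp_pos (boolean), "
                f"got {sorted(cols)}"
            )

    @property
    def dialect(self) -> str:
        return self._dialect

    def __len__(self) -> int:
        return len(self.events)

    def classified(self) -> pd.DataFrame:
        """Boolean (rfp_pos, gfp_pos) per event, gating raw intensities if needed."""
        if self._dialect == "boolean":
            return self.events[["rfp_pos", "gfp_pos"]].astype(bool)
        if self.rfp_threshold is None or self.gfp_threshold is None:
            raise ValueError("raw-intensity events need rfp_threshold and gfp_threshold gates")
        if self.rfp_threshold <= 0 or self.gfp_threshold <= 0:
            raise ValueError("gate thresholds must be positive")
        return pd.DataFrame(
            {
                "rfp_pos": self.events["rfp"] > self.rfp_threshold,
                "gfp_pos": self.events["gfp"] > self.gfp_threshold,
            }
        )


@dataclass(frozen=True)
class PedigreeCounts:
    """Switching events per observed cell division from time-lapse microscopy."""

    genotype: str
    direction: str
    n_divisions: int
    n_events: int

    def __post_init__(self) -> None:
        if self.direction not in (LOSS, ESTABLISHMENT):
            raise ValueError(f"direction must be {LOSS!r} or {ESTABLISHMENT!r}, got {self.direction!r}")
        if self.n_divisions < 0 or not (0 <= self.n_events <= self.n_divisions):
            raise ValueError(
                f"need 0 <= n_events <= n_divisions, got {self.n_events}/{self.n_divisions}"
            )


@dataclass(frozen=True)
class CrashRate:
    """Apparent silencing-loss rate from one CRASH flow sample."""

    rate: float
    n_rfp_gfp: int        # RFP+ GFP+: lost silencing recently
    n_rfp_only: int       # RFP+ GFP-: silenced
    n_gfp_only: int       # RFP- GFP+: lost silencing longer ago (excluded from ratio)
    n_double_neg: int     # reported, excluded


def crash_apparent_loss_rate(pop: FlowPopulation) -> CrashRate:
    """Apparent loss rate: RFP+GFP+ / (RFP+GFP+ + RFP+GFP-).

    Cells that are RFP- GFP+ lost silencing long enough ago for RFP to
    dilute away; they are counted and reported but do not enter the
    ratio, which estimates the per-division loss rate over the RFP
    persistence window.
    """
    cls = pop.classified()
    if len(cls) == 0:
        raise ValueError("flow population has no events after gating")
    rp, gp = cls["rfp_pos"].to_numpy(), cls["gfp_pos"].to_numpy()
    n_both = int((rp & gp).sum())
    n_rfp = int((rp & ~gp).sum())
    n_gfp = int((~rp & gp).sum())
    n_neg = int((~rp & ~gp).sum())
    denom = n_both + n_rfp
    if denom == 0:
        raise ZeroDivisionError("apparent loss rate undefined: no RFP+ cells in sample")
    return CrashRate(rate=n_both / denom, n_rfp_gfp=n_both, n_rfp_only=n_rfp, n_gfp_only=n_gfp, n_double_neg=n_neg)


def crash_rate_summary(pops: list[FlowPopulation]) -> tuple[float, float, list[float]]:
    """Mean ± SD of apparent loss rates across replicate populations.

    Per-replicate rates are returned for downstream ANOVA/Tukey by
    standard statistical routines.
    """
    rates = [crash_apparent_loss_rate(p).rate for p in pops]
    arr = np.asarray(rates)
    sd = float(arr.std(ddof=1)) if len(rates) > 1 else 0.0
    return float(arr.mean()), sd, rates


def gfp_gate_from_controls(
    silenced_gfp: np.ndarray,
    expressed_gfp: np.ndarray,
    gap_fraction: float = 0.2,
) -> tuple[float, float, float]:
    """Calibrate the GFP gate from fully silenced and fully expressed controls.

    The threshold is the log-scale midpoint between the two control
    modes (medians); the returned ``(low, high)`` band spans the central
    ``gap_fraction`` of the log gap and is used to flag events of
    ambiguous state.

    Returns ``(threshold, low, high)`` in intensity units.
    """
    lo_mode = np.log10(max(float(np.median(silenced_gfp)), 1e-12))
    hi_mode = np.log10(max(float(np.median(expressed_gfp)), 1e-12))
    if hi_mode <= lo_mode:
        raise ValueError("expressed control mode must exceed silenced control mode")
    mid = 0.5 * (lo_mode + hi_mode)
    half_band = 0.5 * gap_fraction * (hi_mode - lo_mode)
    return 10 ** mid, 10 ** (mid - half_band), 10 ** (mid + half_band)


@dataclass(frozen=True)
class FlameFractions:
    """Equilibrium state fractions of a FLAME population."""

    pct_silenced: float
    pct_expressed: float
    gap_fraction: float
    poor_separation: bool = False


def flame_equilibrium_fractions(
    pop: FlowPopulation,
    gate_band: tuple[float, float] | None = None,
) -> FlameFractions:
    """Percentages of silenced (GFP-) and expressed (GFP+) cells.

    Raw-intensity populations are gated at ``pop.gfp_threshold``
    (calibrate with :func:`gfp_gate_from_controls`).  When ``gate_band``
    (low, high) is given, the fraction of events inside the band is
    reported as a bimodality/gate-quality index; above 20% a
    :class:`GateSeparationWarning` is emitted and the result flagged.
    """
    if len(pop) == 0:
        raise ValueError("flow population has no events")
    cls = pop.classified()
    gfp = cls["gfp_pos"].to_numpy()
    pct_expressed = 100.0 * gfp.mean()
    gap = 0.0
    if gate_band is not None and pop.dialect == "raw":
        low, high = gate_band
        if not (0 < low <= high):
            raise ValueError("gate_band must satisfy 0 < low <= high")
        g = pop.events["gfp"].to_numpy()
        gap = float(((g > low) & (g < high)).mean())
    poor = gap > 0.2
    if poor:
        warnings.warn(
            f"{gap:.1%} of events fall between the silenced and expressed gates; "
            "gate separation is poor",
            GateSeparationWarning,
            stacklevel=2,
        )
    return FlameFractions(
        pct_silenced=100.0 - pct_expressed,
        pct_expressed=pct_expressed,
        gap_fraction=gap,
        poor_separation=poor,
    )


def pedigree_rate(counts: PedigreeCounts) -> tuple[float, tuple[float, float]]:
    """Per-generation switching rate with a Wilson score 95% CI.

    Point estimate ``n_events / n_divisions``; the Wilson interval keeps
    sensible coverage at the small event counts typical of pedigree data
    (a handful of switches in ~1000 divisions).
    """
    if counts.n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    rate = counts.n_events / counts.n_divisions
    lo, hi = proportion_confint(counts.n_events, counts.n_divisions, alpha=0.05, method="wilson")
    return rate, (float(lo), float(hi))


def compare_rates_yates(a: PedigreeCounts, b: PedigreeCounts) -> tuple[float, float]:
    """Yates continuity-corrected chi-square comparison of two rates.

    Builds the 2x2 table (events, non-events) x (group a, group b) and
    applies the corrected chi-square with 1 df; the correction is
    clipped so the statistic is 0 when ``|ad - bc| < N/2``.
    """
    table = np.array(
        [
            [a.n_events, a.n_divisions - a.n_events],
            [b.n_events, b.n_divisions - b.n_events],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "a margin of the 2x2 table is empty; the chi-square approximation is invalid "
            "(use an exact test)"
        )
    res = stats.chi2_contingency(table, correction=True)
    return float(res.statistic), float(res.pvalue)
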