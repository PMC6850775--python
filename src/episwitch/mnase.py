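"""Nucleosome occupancy profiles from paired-end MNase fragments.

Micrococcal nuclease digests unprotected DNA, leaving ~147 bp
nucleosome-protected fragments.  The processing chain applied to mapped
paired-end fragments is:

1. keep fragments 140–180 bp long (inclusive), i.e. mononucleosomal;
2. stack each retained fragment's midpoint into a per-base histogram;
3. smooth the histogram with a centered 25 bp rolling mean.

Peaks of the smoothed profile mark nucleosome dyad positions.  All
coordinates are 0-based half-open; conversion to 1-based happens only at
bedGraph/wiggle emission (see :mod:`episwitch.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FragmentSet",
    "OccupancyProfile",
    "filter_by_length",
    "midpoint_histogram",
    "smooth",
    "occupancy_pipeline",
    "call_peaks",
]

log = logging.getLogger(__name__)

MONONUCLEOSOME_MIN_BP = 140
MONONUCLEOSOME_MAX_BP = 180
DEFAULT_SMOOTH_WINDOW_BP = 25


@dataclass(frozen=True)
class FragmentSet:
    """Mapped paired-end fragments restricted to a region of interest.

    ``fragments`` holds columns ``chrom``, ``start``, ``end`` (0-based
    half-open).  ``region`` is ``(chrom, start, end)``.
    """

    fragments: pd.DataFrame
    region: tuple[str, int, int]

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required <= set(self.fragments.columns):
            raise ValueError(f"fragments must have columns {sorted(required)}")
        if len(self.fragments) and not (self.fragments["start"] < self.fragments["end"]).all():
            bad = self.fragments.index[self.fragments["start"] >= self.fragments["end"]][0]
            raise ValueError(f"fragment start must be < end (row {bad})")
        chrom, start, end = self.region
        if start >= end:
            raise ValueError(f"region start must be < end, got {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-base midpoint counts over a region, raw and smoothed.

    ``positions[i]`` is the 0-based genomic coordinate of ``raw[i]`` and
    ``smoothed[i]``; ``n_overflow`` counts fragments whose midpoint fell
    outside the region.
    """

    chrom: str
    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None
    window: int | None
    n_overflow: int = 0

    def __post_init__(self) -> None:
        if self.smoothed is not None and len(self.smoothed) != len(self.raw):
            raise ValueError("smoothed and raw profiles must have equal length")
        if len(self.positions) != len(self.raw):
            raise ValueError("positions and raw counts must have equal length")


def filter_by_length(
    frags: FragmentSet,
    min_len: int = MONONUCLEOSOME_MIN_BP,
    max_len: int = MONONUCLEOSOME_MAX_BP,
) -> FragmentSet:
    """Keep fragments with mononucleosomal length (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len must be <= max_len, got {min_len} > {max_len}")
    lengths = frags.lengths
    keep = (lengths >= min_len) & (lengths <= max_len)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_by_length: discarded %d/%d fragments outside [%d, %d] bp",
                 n_drop, len(frags), min_len, max_len)
    return replace(frags, fragments=frags.fragments.loc[keep].reset_index(drop=True))


def midpoint_histogram(frags: FragmentSet) -> OccupancyProfile:
    """Stack fragment midpoints into a per-base histogram over the region.

    The midpoint of ``[start, end)`` is ``floor((start + end) / 2)``;
    each fragment contributes one count at its midpoint.  Midpoints
    outside the region are tallied in ``n_overflow`` and logged.
    """
    chrom, r_start, r_end = frags.region
    positions = np.arange(r_start, r_end)
    starts = frags.fragments["start"].to_numpy(dtype=np.int64)
    ends = frags.fragments["end"].to_numpy(dtype=np.int64)
    mids = (starts + ends) // 2
    in_region = (mids >= r_start) & (mids < r_end)
    n_overflow = int((~in_region).sum())
    if n_overflow:
        log.info("midpoint_histogram: %d midpoints outside %s:%d-%d (overflow bin)",
                 n_overflow, chrom, r_start, r_end)
    counts = np.bincount(mids[in_region] - r_start, minlength=r_end - r_start).astype(float)
    return OccupancyProfile(
        chrom=chrom, positions=positions, raw=counts, smoothed=None, window=None,
        n_overflow=n_overflow,
    )


def smooth(profile: OccupancyProfile, window: int = DEFAULT_SMOOTH_WINDOW_BP) -> OccupancyProfile:
    """Centered rolling mean over ``window`` bp; shrinking windows at edges.

    A window wider than the profile degenerates to the global mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    n = len(profile.raw)
    if n == 0:
        raise ValueError("cannot smooth an empty profile")
    if window >= n:
        smoothed = np.full(n, profile.raw.mean())
    else:
        smoothed = (
            pd.Series(profile.raw)
            .rolling(window=window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return replace(profile, smoothed=smoothed, window=window)


def occupancy_pipeline(
    frags: FragmentSet,
    min_len: int = MONONUCLEOSOME_MIN_BP,
    max_len: int = MONONUCLEOSOME_MAX_BP,
    window: int = DEFAULT_SMOOTH_WINDOW_BP,
) -> OccupancyProfile:
    """Full chain: length filter → midpoint histogram → rolling-mean smooth."""
    return smooth(midpoint_histogram(filter_by_length(frags, min_len, max_len)), window)


def call_peaks(
    profile: OccupancyProfile,
    min_rel_height: float = 0.5,
    min_distance_bp: int = 100,
) -> np.ndarray:
    """Genomic positions of local maxima of the smoothed profile.

    Reports maxima above ``min_rel_height`` of the global maximum and at
    least ``min_distance_bp`` apart (nucleosomes cannot overlap, so
    neighbouring dyads sit >= ~147 bp apart in practice).  This is
    argmax reporting, not a peak-calling model.
    """
    if profile.smoothed is None:
        raise ValueError("call_peaks requires a smoothed profile")
    y = profile.smoothed
    if y.max() <= 0:
        return np.array([], dtype=int)
    idx, _ = signal.find_peaks(y, height=min_rel_height * y.max(), distance=min_distance_bp)
    return profile.positions[idx]
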