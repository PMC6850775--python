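"""Two-state epigenetic switching kinetics and rate estimation.

In a ``sir1∆`` background, *HMR* in each cell occupies one of two
heritable transcriptional states — silenced (GFP-) or expressed (GFP+) —
and switches between them at low per-unit-time rates: ``k_on`` for loss
of silencing (silenced → expressed) and ``k_off`` for establishment
(expressed → silenced).  Assuming equal birth and death rates in the two
states, the expressed fraction ``x_on`` of a population obeys

    dx_on/dt = k_on - (k_on + k_off) * x_on

whose solution from a sorted pure population is

    x_on(t) = E * (1 - exp(-(k_on + k_off) t))               (x_on(0) = 0)
    x_on(t) = E * (1 - exp(-(k_on + k_off) t)) + exp(-...)   (x_on(0) = 1)

with equilibrium ``E = k_on / (k_on + k_off)``.  FACS-sorted silenced and
expressed populations relax toward ``E`` and the two rates are estimated
by nonlinear least squares on the observed GFP+ fractions.  Rates fitted
per hour are converted to per generation by multiplying by the measured
generation time (1.96 h in CSM at 30°C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PER_HOUR",
    "PER_GENERATION",
    "DEFAULT_GENERATION_TIME_HR",
    "TwoStateRates",
    "RelaxationTimeCourse",
    "FitResult",
    "EquilibriumCheck",
    "x_on_predicted",
    "fit_rates",
    "to_per_generation",
    "to_per_hour",
    "equilibrium_check",
    "UnidentifiableError",
    "FitConvergenceError",
]

PER_HOUR = "per_hour"
PER_GENERATION = "per_generation"

#: Doubling time of the reference strain in CSM media at 30°C, hours.
DEFAULT_GENERATION_TIME_HR = 1.96

SORTED_SILENCED = "sorted_silenced"
SORTED_EXPRESSED = "sorted_expressed"

_INITIAL_X = {SORTED_SILENCED: 0.0, SORTED_EXPRESSED: 1.0}


class UnidentifiableError(ValueError):
    """The data cannot constrain the requested rates."""


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge after bounded restarts."""


@dataclass(frozen=True)
class TwoStateRates:
    """Loss and establishment rates with their time unit.

    ``k_on`` is the silencing-loss rate (silenced → expressed) and
    ``k_off`` the establishment rate (expressed → silenced), both per
    hour or per generation.  ``generation_time_hr`` carries the doubling
    time used for unit conversion.
    """

    k_on: float
    k_off: float
    unit: str = PER_HOUR
    generation_time_hr: float = DEFAULT_GENERATION_TIME_HR

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError(f"rates must be non-negative, got k_on={self.k_on}, k_off={self.k_off}")
        if self.unit not in (PER_HOUR, PER_GENERATION):
            raise ValueError(f"unit must be {PER_HOUR!r} or {PER_GENERATION!r}, got {self.unit!r}")
        if self.generation_time_hr <= 0:
            raise ValueError(f"generation_time_hr must be positive, got {self.generation_time_hr}")

    @property
    def equilibrium_expressed(self) -> float:
        """Stationary expressed fraction ``k_on / (k_on + k_off)``."""
        s = self.k_on + self.k_off
        if s == 0:
            raise UnidentifiableError("equilibrium undefined when both rates are zero")
        return self.k_on / s


@dataclass(frozen=True)
class RelaxationTimeCourse:
    """One sorted subpopulation followed over time by flow cytometry.

    ``points`` is an ordered list of ``(t_hours, n_cells, n_gfp_pos)``;
    the observed expressed fraction is ``x_on(t) = n_gfp_pos / n_cells``.
    """

    genotype: str
    replicate_id: str
    initial_state: str
    points: tuple[tuple[float, int, int], ...]

    def __post_init__(self) -> None:
        if self.initial_state not in _INITIAL_X:
            raise ValueError(
                f"initial_state must be {SORTED_SILENCED!r} or {SORTED_EXPRESSED!r}, got {self.initial_state!r}"
            )
        object.__setattr__(self, "points", tuple((float(t), int(n), int(k)) for t, n, k in self.points))
        prev = -math.inf
        for t, n, k in self.points:
            if t < 0:
                raise ValueError(f"time must be >= 0 h, got {t}")
            if t <= prev:
                raise ValueError(f"time points must be strictly increasing within a replicate (at t={t})")
            prev = t
            if n < 1:
                raise ValueError(f"n_cells must be >= 1, got {n} at t={t}")
            if not (0 <= k <= n):
                raise ValueError(f"n_gfp_pos must lie in [0, n_cells], got {k}/{n} at t={t}")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.points])

    @property
    def x_on(self) -> np.ndarray:
        return np.array([k / n for _, n, k in self.points])

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([n for _, n, _ in self.points])

    @property
    def x0(self) -> float:
        return _INITIAL_X[self.initial_state]


@dataclass(frozen=True)
class FitResult:
    """Estimated rates with 95% confidence intervals and fit diagnostics."""

    rates: TwoStateRates
    ci_k_on: tuple[float, float]
    ci_k_off: tuple[float, float]
    rss: float
    n_points: int
    fit_method: str
    genotype: str = ""
    sd_k_on: float | None = None
    sd_k_off: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("ci_k_on", self.ci_k_on), ("ci_k_off", self.ci_k_off)):
            if lo > hi:
                raise ValueError(f"{name} bounds out of order: {lo} > {hi}")
            if lo < 0:
                raise ValueError(f"{name} lower bound negative after clipping: {lo}")


def x_on_predicted(rates: TwoStateRates, t, initial_state: str) -> np.ndarray | float:
    """Closed-form expressed fraction at time ``t`` hours after sorting.

    ``rates`` must be per hour (convert with :func:`to_per_hour` first).
    The degenerate case ``k_on = k_off = 0`` returns the initial value at
    all times.
    """
    if rates.unit != PER_HOUR:
        raise ValueError("x_on_predicted expects per-hour rates; convert with to_per_hour first")
    if initial_state not in _INITIAL_X:
        raise ValueError(f"unknown initial_state {initial_state!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    x0 = _INITIAL_X[initial_state]
    s = rates.k_on + rates.k_off
    if s == 0:
        out = np.full_like(t, x0)
        return float(out) if out.ndim == 0 else out
    eq = rates.k_on / s
    out = eq + (x0 - eq) * np.exp(-s * t)
    return float(out) if out.ndim == 0 else out


def to_per_generation(rates: TwoStateRates) -> TwoStateRates:
    """Convert per-hour rates to per-generation by multiplying by the generation time."""
    if rates.unit == PER_GENERATION:
        warnings.warn("rates already per generation; returning unchanged", stacklevel=2)
        return rates
    g = rates.generation_time_hr
    return replace(rates, k_on=rates.k_on * g, k_off=rates.k_off * g, unit=PER_GENERATION)


def to_per_hour(rates: TwoStateRates) -> TwoStateRates:
    """Inverse of :func:`to_per_generation`."""
    if rates.unit == PER_HOUR:
        warnings.warn("rates already per hour; returning unchanged", stacklevel=2)
        return rates
    g = rates.generation_time_hr
    return replace(rates, k_on=rates.k_on / g, k_off=rates.k_off / g, unit=PER_HOUR)


@dataclass(frozen=True)
class EquilibriumCheck:
    """Internal-consistency comparison between rates and equilibrium fractions.

    At stationarity the expressed:silenced ratio ``E/S`` should equal
    ``k_on/k_off``; ``discrepancy`` is their ratio (1 when perfectly
    consistent).
    """

    e_over_s: float
    kon_over_koff: float
    discrepancy: float


def equilibrium_check(rates: TwoStateRates, pct_silenced: float, pct_expressed: float) -> EquilibriumCheck:
    """Compare equilibrium fractions with the fitted rate ratio.

    ``pct_silenced`` and ``pct_expressed`` are percentages summing to
    100 (±0.5 tolerance for rounded inputs).
    """
    if abs(pct_silenced + pct_expressed - 100.0) > 0.5:
        raise ValueError(
            f"percentages must sum to 100 ± 0.5, got S={pct_silenced} + E={pct_expressed}"
        )
    if rates.k_off <= 0:
        raise UnidentifiableError("k_off must be positive to form k_on/k_off")
    if pct_silenced == 0:
        raise UnidentifiableError("equilibrium unidentifiable: no silenced cells (E/S division by zero)")
    e_over_s = pct_expressed / pct_silenced
    ratio = rates.k_on / rates.k_off
    return EquilibriumCheck(e_over_s=e_over_s, kon_over_koff=ratio, discrepancy=e_over_s / ratio if ratio > 0 else math.inf)


# ---------------------------------------------------------------------------
# Nonlinear least-squares estimation

POOLED = "pooled"
PER_REPLICATE_AVERAGED = "per_replicate_averaged"


def _initial_guess(timecourses: list[RelaxationTimeCourse]) -> tuple[float, float]:
    """Heuristic start: equilibrium from late points, total rate from time to half-equilibrium."""
    t_all = np.concatenate([tc.times for tc in timecourses])
    x_all = np.concatenate([tc.x_on for tc in timecourses])
    t_max = float(t_all.max())
    # equilibrium guess: mean x_on over the last quarter of the time span
    late = t_all >= 0.75 * t_max if t_max > 0 else np.ones_like(t_all, bool)
    eq0 = float(np.clip(x_all[late].mean(), 1e-4, 1 - 1e-4))
    # total-rate guess from the first crossing of half the gap to equilibrium
    t_half = None
    for tc in timecourses:
        gap0 = abs(eq0 - tc.x0)
        if gap0 < 1e-6:
            continue
        crossed = np.abs(tc.x_on - tc.x0) >= 0.5 * gap0
        idx = np.nonzero(crossed & (tc.times > 0))[0]
        if idx.size:
            cand = float(tc.times[idx[0]])
            t_half = cand if t_half is None else min(t_half, cand)
    if t_half is None or t_half <= 0:
        t_half = max(t_max / 4.0, 1e-3)
    s0 = math.log(2.0) / t_half
    return eq0 * s0, (1 - eq0) * s0


def _residuals(params: np.ndarray, timecourses: list[RelaxationTimeCourse]) -> np.ndarray:
    k_on, k_off = params
    rates = TwoStateRates(max(k_on, 0.0), max(k_off, 0.0), PER_HOUR)
    res = []
    for tc in timecourses:
        pred = x_on_predicted(rates, tc.times, tc.initial_state)
        res.append(tc.x_on - np.atleast_1d(pred))
    return np.concatenate(res)


def _fit_once(timecourses: list[RelaxationTimeCourse], start: tuple[float, float]):
    return optimize.least_squares(
        _residuals,
        x0=np.maximum(start, 1e-9),
        bounds=(0.0, np.inf),
        args=(timecourses,),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )


def _fit_pooled(timecourses: list[RelaxationTimeCourse], genotype: str) -> FitResult:
    t_all = np.concatenate([tc.times for tc in timecourses])
    x_all = np.concatenate([tc.x_on for tc in timecourses])
    if len(np.unique(t_all)) < 3:
        raise UnidentifiableError(
            f"genotype {genotype!r}: need >= 3 distinct time points, got {len(np.unique(t_all))}"
        )
    if np.ptp(x_all) == 0:
        raise UnidentifiableError(f"genotype {genotype!r}: all observed x_on identical; rates unidentifiable")

    start = _initial_guess(timecourses)
    result = _fit_once(timecourses, start)
    if not result.success:
        # bounded multi-start with jittered initial values
        rng = np.random.default_rng(0)
        for _ in range(5):
            jitter = np.exp(rng.normal(0.0, 1.0, size=2))
            trial = _fit_once(timecourses, (start[0] * jitter[0], start[1] * jitter[1]))
            if trial.success and (not result.success or trial.cost < result.cost):
                result = trial
        if not result.success:
            raise FitConvergenceError(f"nonlinear least squares did not converge for genotype {genotype!r}")

    k_on, k_off = result.x
    n = x_all.size
    rss = float(2.0 * result.cost)
    dof = max(n - 2, 1)

    # asymptotic 95% CIs from the linearized Jacobian (nls/confint2-style);
    # a singular Jacobian direction yields an infinite half-width
    J = result.jac
    cov = rss / dof * np.linalg.pinv(J.T @ J)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se = np.where(np.isfinite(se), se, np.inf)
    tq = stats.t.ppf(0.975, dof)
    ci_on = (float(max(k_on - tq * se[0], 0.0)), float(k_on + tq * se[0]))
    ci_off = (float(max(k_off - tq * se[1], 0.0)), float(k_off + tq * se[1]))

    return FitResult(
        rates=TwoStateRates(float(k_on), float(k_off), PER_HOUR),
        ci_k_on=ci_on,
        ci_k_off=ci_off,
        rss=rss,
        n_points=n,
        fit_method=POOLED,
        genotype=genotype,
    )


def fit_rates(
    timecourses: list[RelaxationTimeCourse],
    method: str = POOLED,
) -> FitResult:
    """Estimate ``k_on`` and ``k_off`` (per hour) from relaxation time courses.

    ``pooled`` minimizes squared error jointly over every data point of
    every subpopulation — one best-fit curve through all points of a
    genotype.  ``per_replicate_averaged`` fits each subpopulation
    separately and averages the per-replicate rates, reporting their
    standard deviation (``sd_k_on``/``sd_k_off``) and a t-interval on the
    mean as the 95% CI.

    Raises
    ------
    UnidentifiableError
        Fewer than 3 distinct time points, or constant observed x_on.
    FitConvergenceError
        Optimizer failure after bounded jittered restarts.
    """
    if not timecourses:
        raise ValueError("fit_rates requires at least one time course")
    genotype = timecourses[0].genotype
    if method == POOLED:
        return _fit_pooled(timecourses, genotype)
    if method != PER_REPLICATE_AVERAGED:
        raise ValueError(f"unknown fit method {method!r}")

    fits = [_fit_pooled([tc], f"{genotype}/{tc.replicate_id}") for tc in timecourses]
    k_ons = np.array([f.rates.k_on for f in fits])
    k_offs = np.array([f.rates.k_off for f in fits])
    n_rep = len(fits)
    mean_on, mean_off = float(k_ons.mean()), float(k_offs.mean())
    sd_on = float(k_ons.std(ddof=1)) if n_rep > 1 else 0.0
    sd_off = float(k_offs.std(ddof=1)) if n_rep > 1 else 0.0
    tq = stats.t.ppf(0.975, n_rep - 1) if n_rep > 1 else 0.0
    half_on = tq * sd_on / math.sqrt(n_rep) if n_rep > 1 else 0.0
    half_off = tq * sd_off / math.sqrt(n_rep) if n_rep > 1 else 0.0
    return FitResult(
        rates=TwoStateRates(mean_on, mean_off, PER_HOUR),
        ci_k_on=(max(mean_on - half_on, 0.0), mean_on + half_on),
        ci_k_off=(max(mean_off - half_off, 0.0), mean_off + half_off),
        rss=float(sum(f.rss for f in fits)),
        n_points=int(sum(f.n_points for f in fits)),
        fit_method=PER_REPLICATE_AVERAGED,
        genotype=genotype,
        sd_k_on=sd_on,
        sd_k_off=sd_off,
    )
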