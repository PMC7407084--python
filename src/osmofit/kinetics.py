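"""Single-cell growth kinetics from volume trajectories.

The instantaneous growth rate over one imaging interval is
(1/Δt)·ln[V(t+Δt)/V(t)] with Δt converted from minutes to hours, so rates are
specific rates in h⁻¹ — the same convention as the population-level module.
Per-cell means over a fixed imaging window feed population comparisons
(Welch two-tailed t-test, percent difference relative to the reference
group) and the growth-rate-vs-volume ("Growth Law") summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DataError, ParameterError

MIN_PER_HOUR = 60.0


@dataclass
class VolumeTrajectory:
    """Volume time course of one tracked cell (time in minutes, V in µm³)."""

    cell_id: str
    time: np.ndarray
    volume: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.time.shape != self.volume.shape or self.time.ndim != 1:
            raise DataError("time and volume must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise DataError("a trajectory needs at least 2 points")
        if not np.all(np.diff(self.time) > 0):
            raise DataError("time must be strictly increasing")
        if not np.all(self.volume > 0):
            raise DataError("volumes must be positive")


@dataclass(frozen=True)
class CellGrowthRate:
    """Mean instantaneous growth rate of one cell over the imaging window."""

    cell_id: str
    mean_rate: float      # h⁻¹
    n_intervals: int


@dataclass(frozen=True)
class PopulationComparison:
    """Welch t-test comparison of two per-cell growth-rate populations.

    ``percent_difference`` is 100·(mean_b − mean_a)/mean_a, i.e. relative to
    group a (the reference/ancestor).
    """

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    percent_difference: float
    t_statistic: float
    p_two_tailed: float
    n_a: int
    n_b: int


def instantaneous_rates(traj: VolumeTrajectory) -> np.ndarray:
    """Specific growth rate per consecutive imaging interval (h⁻¹).

    Interval-aware: a gap in imaging simply enters as a longer Δt.
    """
    dt_h = np.diff(traj.time) / MIN_PER_HOUR
    return np.log(traj.volume[1:] / traj.volume[:-1]) / dt_h


def cell_mean_rate(traj: VolumeTrajectory, window_min: float) -> CellGrowthRate:
    """Mean instantaneous rate over intervals inside the first ``window_min``.

    Only intervals that end within the window (measured from the trajectory
    start) contribute.  For gap-free sampling of an exact exponential this
    equals the generating rate for any window.
    """
    span = traj.time[-1] - traj.time[0]
    if span < window_min - 1e-9:
        raise CoverageError(
            f"trajectory spans {span:g} min, shorter than the "
            f"{window_min:g}-min window")
    rates = instantaneous_rates(traj)
    ends = traj.time[1:] - traj.time[0]
    inside = ends <= window_min + 1e-9
    if not np.any(inside):
        raise CoverageError("no complete interval inside the window")
    sel = rates[inside]
    return CellGrowthRate(cell_id=traj.cell_id,
                          mean_rate=float(np.mean(sel)),
                          n_intervals=int(inside.sum()))


def population_rates(trajectories: list[VolumeTrajectory],
                     window_min: float) -> list[CellGrowthRate]:
    """``cell_mean_rate`` applied across a population."""
    return [cell_mean_rate(t, window_min) for t in trajectories]


def compare_populations(a: list[CellGrowthRate],
                        b: list[CellGrowthRate]) -> PopulationComparison:
    """Welch (unequal-variance) two-sample two-tailed t-test on mean rates.

    Group a is the reference: the percent difference is how much faster (or
    slower, if negative) group b grows relative to a.  Two zero-variance
    groups with equal means yield p = 1 by convention.
    """
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("need at least 2 cells per group")
    ra = np.array([c.mean_rate for c in a])
    rb = np.array([c.mean_rate for c in b])
    mean_a, mean_b = float(ra.mean()), float(rb.mean())
    sem_a = float(ra.std(ddof=1) / math.sqrt(len(ra)))
    sem_b = float(rb.std(ddof=1) / math.sqrt(len(rb)))
    if ra.std(ddof=1) == 0 and rb.std(ddof=1) == 0:
        tstat = 0.0 if mean_a == mean_b else math.inf
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        res = stats.ttest_ind(rb, ra, equal_var=False)
        tstat, p = float(res.statistic), float(res.pvalue)
    return PopulationComparison(
        mean_a=mean_a, mean_b=mean_b, sem_a=sem_a, sem_b=sem_b,
        percent_difference=100.0 * (mean_b - mean_a) / mean_a,
        t_statistic=tstat, p_two_tailed=p, n_a=len(ra), n_b=len(rb))


@dataclass(frozen=True)
class GrowthLawResult:
    """Tidy rate-vs-volume table with a log-volume-on-rate regression.

    The Growth Law predicts mean cell volume grows exponentially with the
    nutrient-imposed growth rate, i.e. the (rate, ln volume) points of all
    conditions fall on a single line.  The slope, intercept, and R² let that
    prediction be assessed; no biological verdict is made here.
    """

    table: pd.DataFrame
    slope: float          # d ln(volume) / d rate, h
    intercept: float      # ln µm³ at zero rate
    r_squared: float


def growth_law_table(conditions: list[dict]) -> GrowthLawResult:
    """Assemble the growth-rate-vs-volume summary across conditions.

    Each condition is a mapping with keys ``label``, ``mean_volume`` (µm³),
    ``mean_rate`` (h⁻¹) and optionally ``sem_volume`` / ``sem_rate``.
    """
    if len(conditions) < 2:
        raise ParameterError("need at least 2 conditions")
    rows = []
    for c in conditions:
        rows.append({
            "label": c["label"],
            "mean_rate": float(c["mean_rate"]),
            "mean_volume": float(c["mean_volume"]),
            "sem_rate": float(c.get("sem_rate", np.nan)),
            "sem_volume": float(c.get("sem_volume", np.nan)),
        })
    table = pd.DataFrame(rows)
    x = table["mean_rate"].to_numpy()
    y = np.log(table["mean_volume"].to_numpy())
    if np.ptp(x) == 0:
        raise ParameterError("all conditions share the same rate; no fit possible")
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue ** 2) if np.ptp(y) > 0 else 1.0
    return GrowthLawResult(table=table, slope=float(fit.slope),
                           intercept=float(fit.intercept), r_squared=r2)
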