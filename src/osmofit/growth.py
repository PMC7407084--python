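"""Population-level growth-curve kinetics.

Operations on OD600-vs-time curves from plate-reader experiments: blank
subtraction and replicate statistics, instantaneous specific growth rate
(local slope of ln OD), growth rate as a function of OD, Gompertz fitting,
saturation OD, diauxic-shift detection, and a monoculture relative-fitness
statistic defined as the ratio of half the evolved population's saturation OD
to the ancestor's OD at the time (T1/2) the evolved culture reaches
half-saturation.

All specific growth rates are d ln(OD)/dt in h⁻¹.  The Gompertz model used
throughout is the Zwietering sigmoid applied to ln(OD/OD0), so its μmax
parameter is exactly the maximum specific growth rate and its λ the lag time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .errors import (
    AlignmentError,
    DivisionGuardError,
    EmptyCurveError,
    NoCrossingError,
    OutOfRangeError,
    ParameterError,
)

# OD below this (after blank subtraction) is treated as plate-reader noise
# floor: log-rates are undefined there.
OD_FLOOR = 0.005
# Default window (points) for the local log-slope growth-rate estimator.
RATE_WINDOW = 5
# Plateau detection: relative slope (h⁻¹) threshold over the trailing window.
PLATEAU_TOL = 0.01
PLATEAU_WINDOW_H = 2.0
# Shift detection: minimum prominence as a fraction of the global max rate.
MIN_PROMINENCE_FRAC = 0.10

_E = math.e


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """One OD600 time series for a well/condition."""

    time: np.ndarray               # hours, strictly increasing
    od: np.ndarray                 # OD600, same length
    condition: str = ""
    replicate: str | int = 0
    blank: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.od.shape:
            raise ParameterError("time and od must be 1-D arrays of equal length")
        if len(self.time) < 3:
            raise ParameterError("a growth curve needs at least 3 time points")
        if not np.all(np.diff(self.time) > 0):
            raise ParameterError("time must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ParameterError("od values must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class GrowthRateSeries:
    """Specific growth rate (h⁻¹) evaluated along a growth curve.

    ``rate`` is NaN wherever the rate is undefined (OD at or below the floor).
    """

    time: np.ndarray
    od: np.ndarray
    rate: np.ndarray
    od_floor: float = OD_FLOOR

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.od) == len(self.rate)):
            raise ParameterError("time, od, rate must have equal length")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.rate)


@dataclass(frozen=True)
class GompertzFit:
    """Fitted Zwietering-Gompertz parameters for one growth curve.

    ``mu_max`` is the maximum specific growth rate (max d ln OD/dt) of the
    fitted curve; ``mu_max_od`` is the alternative max d(OD)/dt convention,
    reported so either reading of a published maximum rate can be matched.
    """

    A: float                 # saturation OD
    mu_max: float            # h⁻¹, specific-rate convention
    lag: float               # h
    od0: float               # fitted inoculum OD
    rss: float               # residual sum of squares on ln OD
    converged: bool
    mu_max_od: float = float("nan")   # OD·h⁻¹, absolute-slope convention
    message: str = ""

    def predict(self, time: np.ndarray) -> np.ndarray:
        return gompertz_od(np.asarray(time, float), self.A, self.mu_max,
                           self.lag, self.od0)


@dataclass(frozen=True)
class FitnessResult:
    """Monoculture relative fitness of an evolved curve vs its ancestor."""

    od_max_ev: float         # evolved saturation OD
    t_half: float            # h; first time evolved OD reaches od_max_ev / 2
    od_anc_at_t_half: float  # ancestor OD at T1/2 (interpolated)
    fitness: float           # (od_max_ev / 2) / od_anc_at_t_half


@dataclass(frozen=True)
class ShiftResult:
    """Diauxic-shift detection result; ``shifted`` False means no dip found."""

    shifted: bool
    t_shift: float = float("nan")
    rate_at_shift: float = float("nan")
    pre_max_rate: float = float("nan")
    post_max_rate: float = float("nan")


# ---------------------------------------------------------------------------
# Gompertz model (log-OD Zwietering form)
# ---------------------------------------------------------------------------

def gompertz_log_ratio(t: np.ndarray, A: float, mu_max: float, lag: float,
                       od0: float) -> np.ndarray:
    """ln(OD/OD0) of the Zwietering-Gompertz model.

    K = ln(A/od0) is the log dynamic range; μmax is the maximum of
    d ln OD/dt, attained where the inner exponent equals zero.
    """
    K = math.log(A / od0)
    return K * np.exp(-np.exp(mu_max * _E / K * (lag - t) + 1.0))


def gompertz_od(t: np.ndarray, A: float, mu_max: float, lag: float,
                od0: float) -> np.ndarray:
    """OD(t) of the Gompertz model (without baseline)."""
    if mu_max == 0:
        return np.full_like(np.asarray(t, float), od0)
    return od0 * np.exp(gompertz_log_ratio(t, A, mu_max, lag, od0))


def gompertz_specific_rate(t: np.ndarray, A: float, mu_max: float, lag: float,
                           od0: float) -> np.ndarray:
    """Closed-form specific growth rate d ln OD/dt of the Gompertz model."""
    if mu_max == 0:
        return np.zeros_like(np.asarray(t, float))
    K = math.log(A / od0)
    v = np.exp(mu_max * _E / K * (lag - t) + 1.0)
    return K * np.exp(-v) * v * (mu_max * _E / K)


def gompertz_rate_at_od(od: float, A: float, mu_max: float, od0: float) -> float:
    """Closed-form specific rate of the Gompertz model at a given OD."""
    K = math.log(A / od0)
    G = math.log(od / od0)
    if not 0 < G < K:
        raise OutOfRangeError("od outside the open interval (od0, A)")
    return mu_max * _E / K * G * math.log(K / G)


# ---------------------------------------------------------------------------
# preprocessing and replicate statistics
# ---------------------------------------------------------------------------

def preprocess(curves: list[GrowthCurve], blank: float | None = None,
               od_floor: float = OD_FLOOR) -> list[GrowthCurve]:
    """Blank-subtract and floor a set of replicate curves.

    ``blank`` overrides each curve's own ``blank`` attribute when given.
    Values below ``od_floor`` after subtraction are floored there.
    """
    out = []
    for c in curves:
        b = c.blank if blank is None else blank
        od = np.maximum(c.od - b, od_floor)
        out.append(replace(c, od=od, blank=0.0))
    return out


def replicate_stats(curves: list[GrowthCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time-point mean and SEM across replicate curves.

    Curves on different grids are linearly interpolated onto the overlap of
    their time ranges (sampled at the first curve's points).

    Returns
    -------
    time, mean, sem : arrays; SEM uses the n−1 sample standard deviation and
    is zero for a single replicate.
    """
    if not curves:
        raise ParameterError("no curves given")
    t0 = curves[0].time
    lo = max(c.time[0] for c in curves)
    hi = min(c.time[-1] for c in curves)
    if hi <= lo:
        raise AlignmentError("replicate time ranges do not overlap")
    grid = t0[(t0 >= lo - 1e-12) & (t0 <= hi + 1e-12)]
    if len(grid) < 3:
        raise AlignmentError("fewer than 3 common time points across replicates")
    stack = np.vstack([np.interp(grid, c.time, c.od) for c in curves])
    mean = stack.mean(axis=0)
    if len(curves) > 1:
        sem = stack.std(axis=0, ddof=1) / math.sqrt(len(curves))
    else:
        sem = np.zeros_like(mean)
    return grid, mean, sem


def mean_curve(curves: list[GrowthCurve]) -> GrowthCurve:
    """Replicate-mean growth curve (the substrate for fitness and rates)."""
    grid, mean, _ = replicate_stats(curves)
    first = curves[0]
    return GrowthCurve(time=grid, od=mean, condition=first.condition,
                       replicate="mean", meta={"n_replicates": len(curves)})


# ---------------------------------------------------------------------------
# instantaneous growth rate and rate-vs-OD
# ---------------------------------------------------------------------------

def instantaneous_growth_rate(curve: GrowthCurve, window: int = RATE_WINDOW,
                              od_floor: float = OD_FLOOR) -> GrowthRateSeries:
    """Specific growth rate: local least-squares slope of ln OD.

    A centered window of ``window`` points is used at interior points; near
    the ends the window is clipped to the available one-sided points.  The
    rate is NaN where OD is at or below ``od_floor``.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be odd and >= 3")
    n = len(curve)
    if window > n:
        raise ParameterError("window larger than the number of points")
    half = window // 2
    ln_od = np.where(curve.od > od_floor, np.log(np.maximum(curve.od, 1e-300)),
                     np.nan)
    rate = np.full(n, np.nan)
    for i in range(n):
        if not np.isfinite(ln_od[i]):
            continue
        lo, hi = max(0, i - half), min(n - 1, i + half)
        idx = np.arange(lo, hi + 1)
        idx = idx[np.isfinite(ln_od[idx])]
        if len(idx) < 2:
            continue
        t = curve.time[idx]
        y = ln_od[idx]
        tm = t - t.mean()
        denom = float(tm @ tm)
        if denom == 0:
            continue
        rate[i] = float(tm @ (y - y.mean())) / denom
    return GrowthRateSeries(time=curve.time.copy(), od=curve.od.copy(),
                            rate=rate, od_floor=od_floor)


@dataclass
class RateVsOD:
    """(OD, rate) pairs sorted by OD, with linear-in-OD rate queries."""

    od: np.ndarray
    rate: np.ndarray

    def rate_at_od(self, od_query: float) -> float:
        if od_query < self.od[0] or od_query > self.od[-1]:
            raise OutOfRangeError(
                f"OD {od_query} outside observed range "
                f"[{self.od[0]:.4g}, {self.od[-1]:.4g}]")
        return float(np.interp(od_query, self.od, self.rate))

    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.od.tolist(), self.rate.tolist()))


def rate_vs_od(series: GrowthRateSeries) -> RateVsOD:
    """Growth rate as a function of OD, restricted to above-floor points."""
    mask = series.defined() & (series.od > series.od_floor)
    if not np.any(mask):
        raise EmptyCurveError("no defined rates above the OD floor")
    od = series.od[mask]
    rate = series.rate[mask]
    order = np.argsort(od, kind="stable")
    return RateVsOD(od=od[order], rate=rate[order])


def max_growth_rate(series: GrowthRateSeries) -> tuple[float, float]:
    """Maximum of the rate series and the time at which it occurs.

    Ties are broken by the earliest time.
    """
    mask = series.defined()
    if not np.any(mask):
        raise EmptyCurveError("no defined rates in the series")
    rates = np.where(mask, series.rate, -np.inf)
    i = int(np.argmax(rates))          # argmax returns the first maximum
    return float(series.rate[i]), float(series.time[i])


# ---------------------------------------------------------------------------
# Gompertz fitting
# ---------------------------------------------------------------------------

def fit_gompertz(curve: GrowthCurve, od_floor: float = OD_FLOOR) -> GompertzFit:
    """Nonlinear least-squares Gompertz fit on ln OD.

    The model is ln OD(t) = ln od0 + K·exp(−exp(μmax·e/K·(λ−t)+1)) with
    K = ln(A/od0).  Initial values come from the data: od0 from the smallest
    above-floor OD, K from the log dynamic range, μmax from the maximum
    discrete log-slope, and λ from the tangent intercept at that point.
    Non-convergence or a degenerate (flat) curve yields ``converged=False``
    with diagnostics rather than an exception.
    """
    mask = curve.od > od_floor
    if int(mask.sum()) < 6:
        raise ParameterError("need at least 6 above-floor points to fit")
    t = curve.time[mask]
    y = np.log(curve.od[mask])

    span = float(y.max() - y.min())
    if span < math.log(1.2):  # < 20% dynamic range: effectively flat
        return GompertzFit(A=float(np.exp(y.max())), mu_max=0.0, lag=0.0,
                           od0=float(np.exp(y.min())),
                           rss=float(np.sum((y - y.mean()) ** 2)),
                           converged=False, message="flat curve")

    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), 1e-3)
    c0 = float(y.min())
    K0 = span
    t_star = 0.5 * (t[k] + t[k + 1])
    lag0 = t_star - (0.5 * (y[k] + y[k + 1]) - c0) / mu0

    def model(p: np.ndarray, tt: np.ndarray) -> np.ndarray:
        c, K, mu, lam = p
        return c + K * np.exp(-np.exp(mu * _E / K * (lam - tt) + 1.0))

    def resid(p: np.ndarray) -> np.ndarray:
        return model(p, t) - y

    p0 = np.array([c0, K0, mu0, max(lag0, t[0])])
    lower = [c0 - 5.0, 1e-6, 0.0, t[0] - (t[-1] - t[0])]
    upper = [y.max(), 10.0 * K0 + 5.0, 50.0 * mu0, t[-1]]
    p0 = np.clip(p0, lower, upper)
    sol = least_squares(resid, p0, bounds=(lower, upper), xtol=1e-14,
                        ftol=1e-14, gtol=1e-14, max_nfev=2000)
    c, K, mu, lam = sol.x
    od0 = float(np.exp(c))
    A = float(np.exp(c + K))
    rss = float(np.sum(sol.fun ** 2))
    # absolute-slope convention: max d(OD)/dt of the fitted curve
    tt = np.linspace(curve.time[0], curve.time[-1], 2000)
    od_fit = gompertz_od(tt, A, mu, lam, od0)
    mu_od = float(np.max(np.gradient(od_fit, tt)))
    return GompertzFit(A=A, mu_max=float(mu), lag=float(lam), od0=od0,
                       rss=rss, converged=bool(sol.success),
                       mu_max_od=mu_od, message=sol.message)


# ---------------------------------------------------------------------------
# saturation OD and relative fitness
# ---------------------------------------------------------------------------

def saturation_od(curve: GrowthCurve, plateau_tol: float = PLATEAU_TOL,
                  window_h: float = PLATEAU_WINDOW_H,
                  od_floor: float = OD_FLOOR) -> float:
    """Saturation OD: the curve maximum if a trailing plateau is detected,
    otherwise the final OD measurement.

    A plateau is declared when the relative slope |d ln OD/dt| over the
    trailing ``window_h`` hours is below ``plateau_tol`` (h⁻¹).
    """
    t, od = curve.time, curve.od
    sel = t >= t[-1] - window_h
    if int(sel.sum()) < 2:
        sel = np.zeros_like(sel)
        sel[-2:] = True
    tt = t[sel]
    yy = np.log(np.maximum(od[sel], od_floor))
    tm = tt - tt.mean()
    slope = float(tm @ (yy - yy.mean()) / (tm @ tm))
    if abs(slope) < plateau_tol:
        return float(np.max(od))
    return float(od[-1])


def _first_upward_crossing(time: np.ndarray, od: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    if od[0] >= level:
        return float(time[0])
    above = np.nonzero(od >= level)[0]
    if len(above) == 0:
        raise NoCrossingError("curve never reaches the target OD")
    i = int(above[0])
    t0, t1 = time[i - 1], time[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def relative_fitness(evolved: GrowthCurve, ancestor: GrowthCurve,
                     od_floor: float = OD_FLOOR) -> FitnessResult:
    """Relative fitness of an evolved culture against its ancestor.

    fitness = (ODmax_ev / 2) / OD_anc(T1/2), where ODmax_ev is the evolved
    curve's saturation OD and T1/2 the first time the evolved curve reaches
    half of it (linear interpolation between samples).  Both curves must be
    blank-subtracted and overlap in time through T1/2.
    """
    od_max_ev = saturation_od(evolved, od_floor=od_floor)
    half = od_max_ev / 2.0
    t_half = _first_upward_crossing(evolved.time, evolved.od, half)
    if not ancestor.time[0] <= t_half <= ancestor.time[-1]:
        raise AlignmentError("ancestor curve does not cover T1/2")
    od_anc = float(np.interp(t_half, ancestor.time, ancestor.od))
    if od_anc <= od_floor:
        raise DivisionGuardError("ancestor OD at T1/2 is at or below the floor")
    return FitnessResult(od_max_ev=od_max_ev, t_half=t_half,
                         od_anc_at_t_half=od_anc, fitness=half / od_anc)


# ---------------------------------------------------------------------------
# diauxic-shift detection
# ---------------------------------------------------------------------------

def detect_shift(series: GrowthRateSeries,
                 min_prominence_frac: float = MIN_PROMINENCE_FRAC) -> ShiftResult:
    """Locate the growth-rate dip of a diauxic shift.

    The shift time is the deepest interior local minimum of the rate series
    that is flanked on both sides by maxima exceeding it by at least
    ``min_prominence_frac`` times the global maximum rate.  Flat (tied)
    minima resolve to their plateau midpoint.  A monotone or single-phase
    rate series yields a no-shift result.
    """
    mask = series.defined()
    if int(mask.sum()) < 5:
        raise ParameterError("need at least 5 defined rates")
    idx = np.nonzero(mask)[0]
    # restrict to the longest contiguous defined stretch
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    if len(breaks):
        runs = np.split(idx, breaks + 1)
        idx = max(runs, key=len)
    r = series.rate[idx]
    t = series.time[idx]
    prom = min_prominence_frac * float(np.max(r))
    troughs, props = find_peaks(-r, prominence=max(prom, 1e-12),
                                plateau_size=1)
    if len(troughs) == 0:
        return ShiftResult(shifted=False)
    depth = r[troughs]
    best = int(np.argmin(depth))
    # flat valley: centre of the plateau
    le = int(props["left_edges"][best])
    re = int(props["right_edges"][best])
    k = (le + re) // 2
    pre = float(np.max(r[: le + 1])) if le > 0 else float(r[0])
    post = float(np.max(r[re:]))
    return ShiftResult(shifted=True, t_shift=float(t[k]),
                       rate_at_shift=float(r[k]),
                       pre_max_rate=pre, post_max_rate=post)


# ---------------------------------------------------------------------------
# passaging arithmetic
# ---------------------------------------------------------------------------

def generations_per_cycle(dilution_factor: float) -> float:
    """Generations of regrowth per serial-passage cycle: log2 of the dilution.

    A daily 1:100 back-dilution yields log2(100) ≈ 6.6 generations per day.
    """
    if dilution_factor <= 1:
        raise ParameterError("dilution factor must exceed 1")
    return math.log2(dilution_factor)
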