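"""Seeded synthetic data emulating an osmotic-adaptation evolution study.

Three generators with planted ground truth:

* plate-reader OD600 growth curves following the Zwietering-Gompertz model
  applied to ln(OD/OD0) — so the μmax parameter is the maximum specific
  growth rate — with optional multiplicative log-normal noise and an optional
  second (diauxic) growth phase;
* populations of spherocylindrical cells with planted width/length
  distributions, exact boundary contours with optional radial jitter, and
  exponential volume trajectories with per-cell rates drawn from a normal
  distribution;
* population-sequencing mutation tables with planted prevalences and protein
  class labels.

All randomness flows from one root seed through deterministic per-item
substreams, so fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .geometry import Contour, pill_volume, spherocylinder_boundary
from .growth import GrowthCurve, gompertz_log_ratio, gompertz_od
from .kinetics import VolumeTrajectory
from .mutations import MutationRecord

_E = math.e

# gene-name pool for simulated mutation tables (osmotic-adaptation themed)
_GENE_POOL = (
    "topA", "prc", "putA", "putP", "nusA", "rho", "yfdV", "ycfT", "sucA",
    "ftsW", "slyB", "mscL", "phoR", "pstS", "arcA", "arcB", "proP", "proU",
    "ompR", "envZ", "mdoH", "kdpD", "betT", "otsA", "treB",
)
_MUTATION_KINDS = (
    "SNP ({}→{})", "+{}bp insertion", "Δ{}bp deletion",
    "IS1 insertion (+9bp)",
)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimParams:
    """Parameters of a single-phase Gompertz growth-curve simulation.

    ``od0`` is the inoculum OD; the default A/100 mirrors a 1:100 daily
    back-dilution.  ``noise_cv`` is the coefficient of variation of
    multiplicative log-normal measurement noise (0.02 emulates a plate
    reader; 0 gives the exact model curve).
    """

    A: float = 0.5            # carrying-capacity OD600
    mu_max: float = 0.8       # maximum specific growth rate, h⁻¹
    lag: float = 2.0          # lag time λ, h
    t_start: float = 0.0      # h
    t_end: float = 24.0       # h
    dt: float = 0.25          # sampling interval, h (15-min plate-reader cycle)
    noise_cv: float = 0.02
    baseline: float = 0.0     # blank OD offset
    od0: float | None = None  # inoculum OD; default A / 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ParameterError("A must be positive")
        if self.mu_max < 0:
            raise ParameterError("mu_max must be non-negative")
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.t_end <= self.t_start:
            raise ParameterError("t_end must exceed t_start")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be non-negative")
        if self.od0 is not None and not 0 < self.od0 < self.A:
            raise ParameterError("od0 must lie in (0, A)")

    @property
    def inoculum(self) -> float:
        return self.od0 if self.od0 is not None else self.A / 100.0

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)


@dataclass
class DiauxicSimParams:
    """Two-phase (diauxic) growth: phase 1 to its plateau, a pause, phase 2.

    Phase 2 begins at the OD where phase 1 saturates; ``shift_pause`` is the
    duration of the growth-rate dip between the phases (h).
    """

    phase1: GrowthSimParams
    phase2: GrowthSimParams
    shift_pause: float = 1.0

    def __post_init__(self) -> None:
        if self.shift_pause < 0:
            raise ParameterError("phases overlap: shift_pause must be >= 0")


@dataclass
class CellPopSimParams:
    """Population of spherocylindrical cells growing exponentially in volume."""

    n_cells: int = 100
    mean_rate: float = 0.8    # h⁻¹
    sd_rate: float = 0.12     # h⁻¹ (between-cell variation)
    mean_width: float = 1.0   # µm
    cv_width: float = 0.05
    mean_length: float = 3.0  # µm
    cv_length: float = 0.15
    frame_dt: float = 3.0     # min between images
    duration: float = 21.0    # min imaging window
    contour_points: int = 64
    contour_noise: float = 0.0  # radial jitter SD, µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if not self.mean_length >= self.mean_width > 0:
            raise ParameterError("need mean_length >= mean_width > 0")
        if self.frame_dt <= 0:
            raise ParameterError("frame_dt must be positive")
        if self.duration < self.frame_dt:
            raise ParameterError("duration must cover at least one frame")
        if self.sd_rate < 0 or self.cv_width < 0 or self.cv_length < 0:
            raise ParameterError("spreads must be non-negative")
        if self.contour_noise < 0:
            raise ParameterError("contour_noise must be non-negative")


@dataclass
class MutationSimParams:
    """Mutation table with planted prevalences and protein-class labels.

    ``prevalence_values`` and ``class_labels`` must each have one entry per
    mutation; an empty-string class label marks an unclassified gene.
    """

    n_mutations: int
    prevalence_values: list[float] = field(default_factory=list)
    class_labels: list[str] = field(default_factory=list)
    population: str = "So0.5-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalence_values) != self.n_mutations:
            raise ParameterError("prevalence_values length must equal n_mutations")
        if len(self.class_labels) != self.n_mutations:
            raise ParameterError("class_labels length must equal n_mutations")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence_values):
            raise ParameterError("prevalences must lie in [0, 1]")


def load_params(path: str | Path, cls):
    """Load a parameter block from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return cls(**data)


def params_to_file(params, path: str | Path) -> None:
    payload = asdict(params)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, n) - 0.5 * sigma * sigma)


def simulate_growth_curve(params: GrowthSimParams,
                          condition: str = "sim",
                          replicate: str | int = 0) -> GrowthCurve:
    """Single-phase Gompertz growth curve with optional multiplicative noise.

    With ``noise_cv=0`` the curve is exactly
    OD(t) = baseline + od0·exp(K·exp(−exp(μmax·e/K·(λ−t)+1))), K = ln(A/od0);
    the maximum of d ln OD/dt equals μmax.  μmax = 0 yields a flat curve at
    baseline + od0.
    """
    t = params.grid()
    od = gompertz_od(t, params.A, params.mu_max, params.lag, params.inoculum)
    rng = np.random.default_rng(params.seed)
    od = od * _noise_factors(rng, params.noise_cv, len(t))
    return GrowthCurve(time=t, od=params.baseline + od, condition=condition,
                       replicate=replicate,
                       meta={"A": params.A, "mu_max": params.mu_max,
                             "lag": params.lag, "od0": params.inoculum})


def growth_params_for_rate_at_od(
    rate: float, od_query: float, A: float,
    od0: float | None = None, lag: float = 2.0, **kwargs
) -> GrowthSimParams:
    """Gompertz parameters whose specific rate at ``od_query`` equals ``rate``.

    Solves the closed-form rate-vs-OD relation ν(OD) = k·G·ln(K/G) with
    G = ln(OD/od0) and K = ln(A/od0) for the shape constant k, and returns
    the corresponding ``GrowthSimParams`` (μmax = k·K/e).
    """
    od0 = A / 100.0 if od0 is None else od0
    K = math.log(A / od0)
    G = math.log(od_query / od0)
    if not 0 < G < K:
        raise ParameterError("od_query must lie strictly between od0 and A")
    k = rate / (G * math.log(K / G))
    mu_max = k * K / _E
    return GrowthSimParams(A=A, mu_max=mu_max, lag=lag, od0=od0, **kwargs)


def simulate_diauxic_curve(params: DiauxicSimParams,
                           condition: str = "diauxic",
                           replicate: str | int = 0) -> GrowthCurve:
    """Two-phase growth curve: phase 1, a rate pause, then phase 2.

    Phase 1 runs on its own grid; phase 2 starts ``shift_pause`` hours after
    phase 1's grid ends, from the OD phase 1 has reached at that moment, and
    follows its own Gompertz (amplitude anchored so the curve is continuous
    and its maximum specific rate is exactly phase 2's μmax).  If phase 2's
    carrying capacity does not exceed the phase-1 plateau, the curve simply
    continues phase 1's Gompertz — so a zero pause with identical phases
    reproduces the single-phase curve.  Noise (phase 1's ``noise_cv``/seed)
    is applied to the assembled curve.
    """
    p1, p2 = params.phase1, params.phase2
    dt = p1.dt
    t2_start = p1.t_end + params.shift_pause
    t_total_end = t2_start + (p2.t_end - p2.t_start)
    n = int(round((t_total_end - p1.t_start) / dt)) + 1
    t = p1.t_start + dt * np.arange(n)

    od = gompertz_od(t, p1.A, p1.mu_max, p1.lag, p1.inoculum)
    od_base = float(gompertz_od(np.array([t2_start]), p1.A, p1.mu_max,
                                p1.lag, p1.inoculum)[0])
    # engage phase 2 only if its carrying capacity exceeds the phase-1
    # plateau by more than 1% (phase 1 reaches A only asymptotically, so an
    # exact comparison would re-grow the last sliver of phase 1)
    if p2.A > od_base * 1.01 and p2.mu_max > 0:
        after = t >= t2_start - 1e-12
        tau = t[after] - t2_start
        g2 = gompertz_log_ratio(tau, p2.A, p2.mu_max, p2.lag, od_base)
        g2_0 = float(gompertz_log_ratio(np.array([0.0]), p2.A, p2.mu_max,
                                        p2.lag, od_base)[0])
        # anchor at zero so the curve is continuous at the phase boundary;
        # a constant shift of ln OD leaves the specific rate untouched
        od[after] = od_base * np.exp(g2 - g2_0)

    rng = np.random.default_rng(p1.seed)
    od = od * _noise_factors(rng, p1.noise_cv, n)
    return GrowthCurve(
        time=t, od=p1.baseline + od, condition=condition, replicate=replicate,
        meta={"t_phase2_start": t2_start, "pause_start": p1.t_end,
              "pause_mid": p1.t_end + params.shift_pause / 2.0,
              "mu1": p1.mu_max, "mu2": p2.mu_max})


# ---------------------------------------------------------------------------
# cell populations
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, max_tries: int = 1000) -> float:
    """Draw Normal(mean, sd) conditioned on exceeding ``lower``."""
    if sd == 0:
        if mean <= lower:
            raise ParameterError("impossible truncation: mean <= lower with sd=0")
        return mean
    for _ in range(max_tries):
        x = float(rng.normal(mean, sd))
        if x > lower:
            return x
    raise ParameterError("impossible truncation: no draw exceeded the bound")


def simulate_cell_population(
    params: CellPopSimParams,
    population: str = "pop",
) -> tuple[list[Contour], list[VolumeTrajectory]]:
    """Spherocylindrical cells with planted shapes and exponential growth.

    Each cell draws a width and a length (truncated so length >= width) and a
    growth rate g ~ Normal(mean_rate, sd_rate); its contour is the exact
    spherocylinder boundary (uniform arc-length placement) with optional
    radial jitter, random pose; its volume trajectory is V(t) = V0·exp(g·t)
    sampled every ``frame_dt`` minutes over ``duration`` minutes, with V0 the
    pill volume of the drawn shape.  Per-cell RNG substreams make output
    deterministic per seed.
    """
    root = np.random.SeedSequence(params.seed)
    contours: list[Contour] = []
    trajectories: list[VolumeTrajectory] = []
    n_frames = int(math.floor(params.duration / params.frame_dt)) + 1
    times = params.frame_dt * np.arange(n_frames)
    for i, child in enumerate(root.spawn(params.n_cells)):
        rng = np.random.default_rng(child)
        cell_id = f"{population}_{i:04d}"
        width = _truncated_normal(rng, params.mean_width,
                                  params.cv_width * params.mean_width, 0.05)
        length = _truncated_normal(rng, params.mean_length,
                                   params.cv_length * params.mean_length, width)
        g = float(rng.normal(params.mean_rate, params.sd_rate))
        pts, normals = spherocylinder_boundary(width / 2.0, length,
                                               params.contour_points)
        if params.contour_noise > 0:
            pts = pts + normals * rng.normal(0.0, params.contour_noise,
                                             (len(pts), 1))
        angle = float(rng.uniform(0.0, math.pi))
        rot = np.array([[math.cos(angle), -math.sin(angle)],
                        [math.sin(angle), math.cos(angle)]])
        offset = rng.uniform(0.0, 50.0, 2)
        pts = pts @ rot.T + offset
        contours.append(Contour(points=pts, cell_id=cell_id))
        v0 = pill_volume(width, length)
        volume = v0 * np.exp(g * times / 60.0)   # g in h⁻¹, times in min
        trajectories.append(VolumeTrajectory(cell_id=cell_id,
                                             time=times.copy(), volume=volume,
                                             meta={"true_rate": g,
                                                   "width": width,
                                                   "length": length}))
    return contours, trajectories


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def simulate_mutation_table(params: MutationSimParams) -> list[MutationRecord]:
    """Mutation records with planted prevalences, genes, and class labels."""
    rng = np.random.default_rng(params.seed)
    genome_length = 4_629_812   # E. coli REL606 chromosome size
    positions = np.sort(rng.choice(genome_length, size=params.n_mutations,
                                   replace=False)) + 1
    records = []
    for i in range(params.n_mutations):
        gene = _GENE_POOL[int(rng.integers(len(_GENE_POOL)))]
        kind = _MUTATION_KINDS[int(rng.integers(len(_MUTATION_KINDS)))]
        if "SNP" in kind:
            a, b = rng.choice(4, size=2, replace=False)
            desc = kind.format(_BASES[a], _BASES[b])
        elif "{}" in kind:
            desc = kind.format(int(rng.integers(1, 13)))
        else:
            desc = kind
        records.append(MutationRecord(
            population=params.population,
            position=int(positions[i]),
            gene=gene,
            mutation=desc,
            prevalence=float(params.prevalence_values[i]),
            protein_class=params.class_labels[i],
        ))
    return records
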