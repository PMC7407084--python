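# osmofit

Quantitative analysis toolkit for serial-passage evolution experiments in
high-osmolarity media — the kind of study in which *E. coli* populations are
passaged for hundreds of generations in minimal medium supplemented with an
osmolyte (sorbitol, proline, sucrose, glycine betaine, NaCl) and their
adaptation is read out from plate-reader growth curves, single-cell
time-lapse imaging, and population sequencing.

It is written for microbial physiologists and experimental-evolution labs
who have three kinds of data and need the standard computations on each:

* **Growth-curve kinetics** (`osmofit.growth`) — blank subtraction and
  replicate SEM, instantaneous specific growth rate μ(t) = d ln OD/dt (local
  least-squares slope of ln OD over a centred window), growth rate as a
  function of OD₆₀₀, Gompertz fitting, saturation OD, diauxic-shift
  detection, and a monoculture **relative-fitness statistic**

  > fitness = (OD_max^ev / 2) / OD^anc(T₁/₂)

  where OD_max^ev is the evolved culture's saturation OD and T₁/₂ the time it
  first reaches half of it. This metric suits slow-saturating
  high-osmolarity cultures where competition assays and full saturation are
  impractical.

* **Single-cell morphometrics and kinetics** (`osmofit.geometry`,
  `osmofit.kinetics`) — from each cell's boundary contour: the pole-to-pole
  midline, mean width 2R (perpendicular chords, excluding polar caps and
  septation sites), length L, and the pill (spherocylinder) volume
  V = πR²(L − 2R) + (4/3)πR³; from each cell's volume trajectory: the
  instantaneous growth rate (1/Δt)·ln[V(t+Δt)/V(t)], per-cell means over an
  imaging window, Welch two-tailed t-tests between populations, and the
  growth-rate-vs-volume ("Growth Law") summary.

* **Mutation-table summaries** (`osmofit.mutations`) — prevalence filtering
  (boundary-inclusive: mutations present at <5% of reads are dropped) and
  prevalence-weighted protein-class histograms with an explicit
  "unclassified" bin.

A seeded synthetic-data generator (`osmofit.synthetic`) produces all three
data types with planted ground truth — Gompertz growth curves (the
Zwietering sigmoid applied to ln OD, so μmax is the maximum specific growth
rate), two-phase diauxic curves, spherocylindrical cell populations growing
exponentially in volume, and mutation tables — so every analysis can be
validated by parameter recovery.

## Worked example

```python
from osmofit import (GrowthSimParams, simulate_growth_curve, fit_gompertz,
                     relative_fitness, instantaneous_growth_rate, rate_vs_od,
                     generations_per_cycle)

anc = simulate_growth_curve(GrowthSimParams(A=0.45, mu_max=0.43, lag=3.0,
                                            noise_cv=0.0), condition="ancestor")
evo = simulate_growth_curve(GrowthSimParams(A=0.60, mu_max=0.58, lag=2.5,
                                            noise_cv=0.0), condition="evolved")

fit = fit_gompertz(evo)
print(f"Gompertz fit (evolved): A = {fit.A:.3f} OD, "
      f"mu_max = {fit.mu_max:.3f} 1/h, lag = {fit.lag:.2f} h")

res = relative_fitness(evo, anc)
print(f"relative fitness = {res.fitness:.3f}  (ODmax_ev = {res.od_max_ev:.3f}, "
      f"T1/2 = {res.t_half:.2f} h, anc OD = {res.od_anc_at_t_half:.4f})")

rv = rate_vs_od(instantaneous_growth_rate(evo))
print(f"evolved rate at OD 0.2 = {rv.rate_at_od(0.2):.3f} 1/h")
print(f"generations per 1:100 cycle = {generations_per_cycle(100):.2f}")
```

prints

```
Gompertz fit (evolved): A = 0.600 OD, mu_max = 0.580 1/h, lag = 2.50 h
relative fitness = 2.897  (ODmax_ev = 0.595, T1/2 = 10.68 h, anc OD = 0.1027)
evolved rate at OD 0.2 = 0.328 1/h
generations per 1:100 cycle = 6.64
```

The fitter recovers the planted parameters exactly on noise-free input (the
curve is generated from the same model family). The fitness of 2.897 says
that at the moment the evolved culture reached half its saturation OD
(0.595/2 ≈ 0.30 at 10.7 h), the ancestor stood at OD 0.103 — the evolved
culture is ~2.9-fold ahead at that reference point. The rate at OD 0.2
(0.328 h⁻¹) is below the evolved μmax of 0.58 h⁻¹ because a Gompertz culture
at one third of saturation has already decelerated. A 1:100 daily dilution
allows log₂(100) ≈ 6.64 doublings per cycle.

## Command line

Every analysis is also exposed as a subcommand of the `osmofit` entry
point: `demo` (seeded end-to-end run regenerating all synthetic datasets),
`fitness`, `growthrate`, `gompertz`, `shift`, `geometry`, `kinetics`, and
`mutations`. For example:

```sh
osmofit demo --seed 7 --out runs/demo1
osmofit gompertz --input runs/demo1/growth_curves.csv --out fit.json
osmofit kinetics --trajectories runs/demo1/trajectories.csv \
    --window 21 --compare ancestor:evolved --out comparison.json
```

File formats are plain text throughout: long/wide growth-curve CSV, contour
CSV (`cell_id, point_index, x_um, y_um`), trajectory CSV
(`cell_id, time_min, volume_um3`), and mutation TSV
(`population, position, gene, mutation, prevalence, protein_class`).

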