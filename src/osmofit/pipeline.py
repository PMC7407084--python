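"""End-to-end seeded demo pipeline.

Regenerates all synthetic datasets (growth curves, a diauxic curve, cell
populations, a mutation table), runs every analysis stage, and writes a
report directory of CSV/JSON tables plus a run manifest with output hashes.
Stages are independent: a failing stage is logged and marked failed without
aborting the others.  Re-running with the same config is bit-identical
(manifest timing fields aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import growth, io, kinetics, mutations, synthetic
from .errors import ParameterError
from .geometry import shape_from_contour

log = logging.getLogger("osmofit")

ALL_STAGES = ("growth", "shift", "cells", "mutations")


@dataclass
class PipelineConfig:
    """Demo-run configuration: seed, stage selection, module parameters."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    rate_window: int = growth.RATE_WINDOW
    volume_formula: str = "spherocylinder"
    min_prevalence: float = mutations.DEFAULT_PREVALENCE_THRESHOLD
    kinetics_window_min: float = 21.0
    n_replicates: int = 4
    noise_cv: float = 0.02
    n_cells: int = 60

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_demo(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the configured stages; return the manifest dict (also written)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "config": dataclasses.asdict(config), "stages": {}}
    runners = {"growth": _stage_growth, "shift": _stage_shift,
               "cells": _stage_cells, "mutations": _stage_mutations}
    for stage in config.stages:
        t0 = time.perf_counter()
        entry: dict = {"status": "ok", "outputs": {}}
        try:
            files = runners[stage](config, out)
            entry["outputs"] = {f.name: _sha256(f) for f in files}
        except Exception as exc:  # stage isolation is the contract here
            log.exception("stage %s failed", stage)
            entry = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
        log.info("stage %s: %s (%.2fs)", stage, entry["status"],
                 entry["elapsed_s"])
    _dump_json(manifest, out / "run_manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_growth(cfg: PipelineConfig, out: Path) -> list[Path]:
    """Ancestor/evolved replicate curves → fitness, Gompertz, rate-vs-OD."""
    anc_curves = [synthetic.simulate_growth_curve(
        synthetic.GrowthSimParams(A=0.45, mu_max=0.43, lag=3.0,
                                  noise_cv=cfg.noise_cv,
                                  seed=cfg.seed * 1000 + r),
        condition="ancestor", replicate=r)
        for r in range(cfg.n_replicates)]
    evo_curves = [synthetic.simulate_growth_curve(
        synthetic.GrowthSimParams(A=0.60, mu_max=0.58, lag=2.5,
                                  noise_cv=cfg.noise_cv,
                                  seed=cfg.seed * 1000 + 500 + r),
        condition="evolved", replicate=r)
        for r in range(cfg.n_replicates)]
    io.write_growth_csv(anc_curves + evo_curves, out / "growth_curves.csv")
    anc = growth.mean_curve(growth.preprocess(anc_curves))
    evo = growth.mean_curve(growth.preprocess(evo_curves))
    fit = growth.relative_fitness(evo, anc)
    _dump_json(dataclasses.asdict(fit), out / "fitness.json")
    gfits = {name: dataclasses.asdict(growth.fit_gompertz(c))
             for name, c in (("ancestor", anc), ("evolved", evo))}
    _dump_json(gfits, out / "gompertz.json")
    series = growth.instantaneous_growth_rate(evo, window=cfg.rate_window)
    rv = growth.rate_vs_od(series)
    import pandas as pd
    pd.DataFrame({"od600": rv.od, "rate_per_h": rv.rate}).to_csv(
        out / "rate_vs_od.csv", index=False)
    return [out / "growth_curves.csv", out / "fitness.json",
            out / "gompertz.json", out / "rate_vs_od.csv"]


def _stage_shift(cfg: PipelineConfig, out: Path) -> list[Path]:
    """Diauxic glucose→osmolyte curve and its shift detection."""
    params = synthetic.DiauxicSimParams(
        phase1=synthetic.GrowthSimParams(A=0.05, mu_max=0.8, lag=2.0,
                                         t_end=10.0, od0=0.005,
                                         noise_cv=cfg.noise_cv,
                                         seed=cfg.seed * 1000 + 77),
        phase2=synthetic.GrowthSimParams(A=0.5, mu_max=0.5, lag=1.0,
                                         t_end=14.0, noise_cv=0.0),
        shift_pause=1.0)
    curve = synthetic.simulate_diauxic_curve(params)
    io.write_growth_csv([curve], out / "diauxic_curve.csv")
    series = growth.instantaneous_growth_rate(curve, window=cfg.rate_window)
    res = growth.detect_shift(series)
    _dump_json(dataclasses.asdict(res), out / "shift.json")
    return [out / "diauxic_curve.csv", out / "shift.json"]


def _stage_cells(cfg: PipelineConfig, out: Path) -> list[Path]:
    """Cell populations → shapes, per-cell rates, comparison, Growth Law."""
    import pandas as pd
    pops = {
        "ancestor": synthetic.CellPopSimParams(
            n_cells=cfg.n_cells, mean_rate=0.8, sd_rate=0.12,
            mean_width=0.9, mean_length=2.8, seed=cfg.seed * 1000 + 11),
        "evolved": synthetic.CellPopSimParams(
            n_cells=cfg.n_cells, mean_rate=0.8 * 1.32, sd_rate=0.16,
            mean_width=1.0, mean_length=3.2, seed=cfg.seed * 1000 + 12),
    }
    all_contours, all_trajs, shapes, rates = [], [], [], {}
    for name, p in pops.items():
        contours, trajs = synthetic.simulate_cell_population(p, population=name)
        all_contours += contours
        all_trajs += trajs
        shapes += [shape_from_contour(c, formula=cfg.volume_formula)
                   for c in contours]
        rates[name] = kinetics.population_rates(trajs, cfg.kinetics_window_min)
    io.write_contours_csv(all_contours, out / "contours.csv")
    io.write_trajectories_csv(all_trajs, out / "trajectories.csv")
    io.write_shapes_csv(shapes, out / "shapes.csv")
    comp = kinetics.compare_populations(rates["ancestor"], rates["evolved"])
    _dump_json(dataclasses.asdict(comp), out / "comparison.json")
    by_pop = {}
    for s in shapes:
        by_pop.setdefault(s.cell_id.split("_")[0], []).append(s.volume)
    conditions = []
    for name in pops:
        vols = by_pop[name]
        rr = [c.mean_rate for c in rates[name]]
        conditions.append({
            "label": name,
            "mean_volume": sum(vols) / len(vols),
            "mean_rate": sum(rr) / len(rr)})
    law = kinetics.growth_law_table(conditions)
    law.table.assign(slope=law.slope, r_squared=law.r_squared).to_csv(
        out / "growth_law.csv", index=False)
    pd.DataFrame([{"cell_id": c.cell_id, "population": pop,
                   "mean_rate_per_h": c.mean_rate,
                   "n_intervals": c.n_intervals}
                  for pop, cells in rates.items() for c in cells]).to_csv(
        out / "cell_rates.csv", index=False)
    return [out / p for p in ("contours.csv", "trajectories.csv",
                              "shapes.csv", "comparison.json",
                              "growth_law.csv", "cell_rates.csv")]


def _stage_mutations(cfg: PipelineConfig, out: Path) -> list[Path]:
    """Planted mutation table → filter, prevalence-weighted histogram."""
    import pandas as pd
    params = synthetic.MutationSimParams(
        n_mutations=8,
        prevalence_values=[0.833, 0.176, 0.65, 0.21, 0.15, 0.35, 0.04, 0.05],
        class_labels=["isomerase", "protease", "transcription factor",
                      "transporter", "", "", "transporter", ""],
        seed=cfg.seed * 1000 + 29)
    records = synthetic.simulate_mutation_table(params)
    io.write_mutations_tsv(records, out / "mutations.tsv")
    kept = mutations.filter_prevalence(records, cfg.min_prevalence)
    hist = mutations.class_histogram(kept)
    pd.DataFrame(sorted(hist.fractions.items())).rename(
        columns={0: "protein_class", 1: "fraction"}).assign(
        weight=lambda d: d["protein_class"].map(hist.entries)).to_csv(
        out / "class_histogram.csv", index=False)
    _dump_json({"n_total": len(records), "n_kept": len(kept),
                "unclassified_fraction": mutations.unclassified_fraction(hist)},
               out / "mutation_summary.json")
    return [out / "mutations.tsv", out / "class_histogram.csv",
            out / "mutation_summary.json"]
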