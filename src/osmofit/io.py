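"""Plain-text dialects for growth curves, contours, trajectories, mutations.

Growth curves: CSV, long layout (condition, replicate, time_h, od600) or wide
layout (time_h plus one OD column per well).  Contours: CSV (cell_id,
point_index, x_um, y_um), points ordered around the boundary, implicitly
closed.  Trajectories: CSV (cell_id, time_min, volume_um3).  Mutation tables:
TSV (population, position, gene, mutation, prevalence as a fraction,
protein_class; empty = unclassified).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .geometry import CellShape, Contour
from .growth import GrowthCurve
from .kinetics import VolumeTrajectory
from .mutations import MutationRecord

MUTATION_COLUMNS = ["population", "position", "gene", "mutation",
                    "prevalence", "protein_class"]


def _fmt(v) -> str:
    """Shortest round-trip decimal representation of a float."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def write_growth_csv(curves: list[GrowthCurve], path: str | Path,
                     layout: str = "long") -> None:
    if layout == "long":
        frames = [pd.DataFrame({"condition": c.condition,
                                "replicate": c.replicate,
                                "time_h": c.time, "od600": c.od})
                  for c in curves]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_fmt)
    elif layout == "wide":
        base = curves[0].time
        data = {"time_h": base}
        for c in curves:
            if len(c.time) != len(base) or not np.allclose(c.time, base):
                raise DataError("wide layout requires a shared time grid")
            data[f"{c.condition}:{c.replicate}"] = c.od
        pd.DataFrame(data).to_csv(path, index=False, float_format=_fmt)
    else:
        raise DataError(f"unknown layout {layout!r}")


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = set(df.columns)
    if {"time_h", "od600"} <= cols:
        curves = []
        keys = [k for k in ("condition", "replicate") if k in cols]
        if keys:
            for name, grp in df.groupby(keys, sort=False):
                name = name if isinstance(name, tuple) else (name,)
                info = dict(zip(keys, name))
                curves.append(GrowthCurve(
                    time=grp["time_h"].to_numpy(),
                    od=grp["od600"].to_numpy(),
                    condition=str(info.get("condition", "")),
                    replicate=info.get("replicate", 0)))
        else:
            curves.append(GrowthCurve(time=df["time_h"].to_numpy(),
                                      od=df["od600"].to_numpy()))
        return curves
    if "time_h" in cols:
        t = df["time_h"].to_numpy()
        curves = []
        for col in df.columns:
            if col == "time_h":
                continue
            cond, _, rep = col.partition(":")
            curves.append(GrowthCurve(time=t, od=df[col].to_numpy(),
                                      condition=cond, replicate=rep or 0))
        return curves
    raise DataError("growth CSV needs a time_h column")


# ---------------------------------------------------------------------------
# contours and shapes
# ---------------------------------------------------------------------------

def write_contours_csv(contours: list[Contour], path: str | Path) -> None:
    frames = []
    for i, c in enumerate(contours):
        cid = c.cell_id if c.cell_id is not None else f"cell_{i:04d}"
        frames.append(pd.DataFrame({
            "cell_id": cid,
            "point_index": np.arange(len(c.points)),
            "x_um": c.points[:, 0], "y_um": c.points[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_fmt)


def read_contours_csv(path: str | Path) -> list[Contour]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"cell_id", "point_index", "x_um", "y_um"}
    if not needed <= set(df.columns):
        raise DataError(f"contour CSV needs columns {sorted(needed)}")
    contours = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("point_index")
        contours.append(Contour(points=grp[["x_um", "y_um"]].to_numpy(),
                                cell_id=str(cid)))
    return contours


def write_shapes_csv(shapes: list[CellShape], path: str | Path) -> None:
    pd.DataFrame([{
        "cell_id": s.cell_id, "width_um": s.width, "length_um": s.length,
        "volume_um3": s.volume, "degenerate": s.degenerate}
        for s in shapes]).to_csv(path, index=False, float_format=_fmt)


# ---------------------------------------------------------------------------
# volume trajectories
# ---------------------------------------------------------------------------

def write_trajectories_csv(trajectories: list[VolumeTrajectory],
                           path: str | Path) -> None:
    frames = [pd.DataFrame({"cell_id": t.cell_id, "time_min": t.time,
                            "volume_um3": t.volume}) for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_fmt)


def read_trajectories_csv(path: str | Path) -> list[VolumeTrajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"cell_id", "time_min", "volume_um3"}
    if not needed <= set(df.columns):
        raise DataError(f"trajectory CSV needs columns {sorted(needed)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        out.append(VolumeTrajectory(cell_id=str(cid),
                                    time=grp["time_min"].to_numpy(),
                                    volume=grp["volume_um3"].to_numpy()))
    return out


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def write_mutations_tsv(records: list[MutationRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "population": r.population, "position": r.position, "gene": r.gene,
        "mutation": r.mutation, "prevalence": r.prevalence,
        "protein_class": r.protein_class}
        for r in records]).to_csv(path, sep="\t", index=False,
                                  columns=MUTATION_COLUMNS, float_format=_fmt)


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_class": str},
                     keep_default_na=False, float_precision="round_trip")
    if not set(MUTATION_COLUMNS) <= set(df.columns):
        raise DataError(f"mutation TSV needs columns {MUTATION_COLUMNS}")
    return [MutationRecord(population=str(row.population),
                           position=int(row.position), gene=str(row.gene),
                           mutation=str(row.mutation),
                           prevalence=float(row.prevalence),
                           protein_class=str(row.protein_class))
            for row in df.itertuples(index=False)]


def read_class_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Gene→protein-class mapping (TSV with columns gene, protein_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene", "protein_class"} <= set(df.columns):
        raise DataError("annotation TSV needs columns gene, protein_class")
    return dict(zip(df["gene"], df["protein_class"]))
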