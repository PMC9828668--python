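"""Readers and writers for the measurement/cell/species CSVs and newick trees.

Dialects: RFC-4180 CSV, UTF-8, mandatory header row; newick with branch
lengths.  Units are fixed: micrometres for lengths, cubic micrometres for
volumes.  Species names are matched to tree tips exactly after a
normalization pass that treats underscores and spaces as equivalent.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .geometry import (
    MEASUREMENT_KINDS,
    CellRecord,
    GyreMeasurement,
    MeasurementError,
)

__all__ = [
    "RunConfig",
    "read_measurements",
    "read_cell_records",
    "read_species",
    "read_tree",
    "read_truth",
    "measurements_frame",
    "cells_frame",
    "write_bundle",
    "normalize_species",
    "load_config",
]

MEASUREMENT_COLUMNS = [
    "cell_id",
    "species",
    "family",
    "gyre_index",
    "half",
    "kind",
    "value_um",
    "center_position_um",
    "obscured",
]
CELL_COLUMNS = [
    "cell_id",
    "species",
    "family",
    "midpiece_um",
    "tail_um",
    "nucleus_diameter_um",
    "obscured_sections_um",
]
SPECIES_COLUMNS = ["species", "head_um", "midpiece_um", "tail_um"]


def normalize_species(name: str) -> str:
    return name.strip().replace(" ", "_")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    measurements: str
    cells: str
    species: str
    tree: str
    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    subset_fraction: float = 0.25
    exclusions: list[str] = field(default_factory=list)
    excluded_family: str = "Turdidae"
    lambda_grid: int = 101
    bootstrap_draws: int = 1000
    stages: list[str] = field(
        default_factory=lambda: [
            "allometry",
            "tapering",
            "gyre_interval",
            "volume",
            "tail_diameter",
            "nucleus",
        ]
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.subset_fraction <= 0.5:
            raise ValueError("subset_fraction must be in (0, 0.5]")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a mapping")
    return RunConfig(**data)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_measurements(path) -> pd.DataFrame:
    """Raw measurement table with schema validation and row-addressed errors."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no records")
    _require_columns(df, MEASUREMENT_COLUMNS, path)
    errors = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        if row["kind"] not in MEASUREMENT_KINDS:
            errors.append(f"row {rowno}: unknown kind {row['kind']!r}")
            continue
        obscured = bool(row["obscured"])
        if not obscured:
            try:
                v = float(row["value_um"])
            except (TypeError, ValueError):
                errors.append(f"row {rowno}: non-numeric width {row['value_um']!r}")
                continue
            if not np.isfinite(v) or v <= 0:
                errors.append(f"row {rowno}: non-positive width {v}")
    dup = df.duplicated(subset=["cell_id", "gyre_index", "half", "kind"])
    for i in df.index[dup]:
        errors.append(
            f"row {i + 2}: duplicate (cell, gyre, half, kind) key"
        )
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors[:20]))
    return df


def _parse_sections(raw) -> list[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return []
    return [float(tok) for tok in str(raw).split(";") if tok.strip() != ""]


def read_cell_records(measurements_path, cells_path) -> list[CellRecord]:
    """Typed cell records assembled from the measurement and cell tables."""
    mdf = read_measurements(measurements_path)
    cdf = pd.read_csv(cells_path, float_precision="round_trip")
    if cdf.empty:
        raise ValueError(f"{cells_path}: no records")
    _require_columns(cdf, CELL_COLUMNS, cells_path)
    cells: list[CellRecord] = []
    grouped = dict(tuple(mdf.groupby("cell_id", sort=False)))
    for i, row in cdf.iterrows():
        cid = row["cell_id"]
        sub = grouped.get(cid)
        ms: list[GyreMeasurement] = []
        if sub is not None:
            for _, r in sub.iterrows():
                obscured = bool(r["obscured"])
                value = None if obscured else float(r["value_um"])
                pos = (
                    None
                    if pd.isna(r["center_position_um"])
                    else float(r["center_position_um"])
                )
                ms.append(
                    GyreMeasurement(
                        cell_id=str(cid),
                        gyre_index=int(r["gyre_index"]),
                        half=int(r["half"]),
                        kind=str(r["kind"]),
                        value_um=value,
                        center_position_um=pos,
                        obscured=obscured,
                    )
                )
        nucleus = row["nucleus_diameter_um"]
        cell = CellRecord(
            cell_id=str(cid),
            species=str(row["species"]),
            family=str(row["family"]),
            measurements=ms,
            midpiece_length_um=float(row["midpiece_um"]),
            tail_length_um=float(row["tail_um"]),
            nucleus_diameter_um=None if pd.isna(nucleus) else float(nucleus),
            obscured_sections_um=_parse_sections(row["obscured_sections_um"]),
        )
        try:
            cell.validate()
        except MeasurementError as exc:
            raise ValueError(f"{cells_path} row {i + 2}: {exc}") from exc
        cells.append(cell)
    return cells


def read_species(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no records")
    _require_columns(df, SPECIES_COLUMNS, path)
    df["species"] = df["species"].map(normalize_species)
    return df


def read_tree(path, species: Optional[Sequence[str]] = None) -> dendropy.Tree:
    """Rooted newick tree with branch lengths; optional tip matching."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tips = [leaf.taxon for leaf in tree.leaf_node_iter()]
    if any(t is None or not t.label for t in tips):
        raise ValueError(f"{path}: tree has unlabelled tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(f"{path}: tree has edges without branch lengths")
    for t in tips:
        t.label = normalize_species(t.label)
    if species is not None:
        want = {normalize_species(s) for s in species}
        have = {t.label for t in tips}
        missing = sorted(want - have)
        if missing:
            raise ValueError(f"{path}: species absent from tree: {missing}")
    return tree


def read_truth(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def measurements_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        for m in c.measurements:
            rows.append(
                {
                    "cell_id": m.cell_id,
                    "species": c.species,
                    "family": c.family,
                    "gyre_index": m.gyre_index,
                    "half": m.half,
                    "kind": m.kind,
                    "value_um": m.value_um,
                    "center_position_um": m.center_position_um,
                    "obscured": m.obscured,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def cells_frame(cells: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "species": c.species,
                "family": c.family,
                "midpiece_um": c.midpiece_length_um,
                "tail_um": c.tail_length_um,
                "nucleus_diameter_um": c.nucleus_diameter_um,
                "obscured_sections_um": ";".join(
                    repr(v) for v in c.obscured_sections_um
                ),
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def write_bundle(bundle, out_dir) -> dict:
    """Write the four input files plus the truth record; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "cells": out / "cells.csv",
        "species": out / "species.csv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    bundle.measurements.to_csv(paths["measurements"], index=False)
    bundle.cell_table.to_csv(paths["cells"], index=False)
    bundle.species_table.to_csv(paths["species"], index=False)
    newick = bundle.tree.as_string(schema="newick", suppress_rooting=True)
    paths["tree"].write_text(newick, encoding="utf-8")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
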