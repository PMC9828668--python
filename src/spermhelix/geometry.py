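"""Geometric reconstruction of mitochondrial-helix volume from SEM width series.

Passerine sperm cells carry a single elongated mitochondrion wound helically
around the flagellum in the midpiece.  On a scanning electron micrograph the
helix presents, per half-gyre, a minimum width (the bare flagellum) and a
maximum width (flagellum plus the helix's minor axis); where the helix passes
over the flagellum its major axis can be measured once per gyre.  This module
turns such width/position series into per-gyre and whole-cell helix volumes:

* the helix cross-section is approximated as an ellipse
  (area = pi * major/2 * minor/2);
* the helix path length within one gyre is the hypotenuse of the gyre
  interval (pitch) and the flagellum circumference (pi * flagellum diameter);
* per-gyre volume = cross-section area x path length, summed over gyres;
* widths missing at single points are imputed with the cell mean of that
  measurement kind, and gyres hidden under debris are counted from the
  obscured-section length and assigned the mean per-gyre volume.

All lengths are micrometres, volumes cubic micrometres.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Optional, Sequence

__all__ = [
    "FLAGELLUM_WIDTH",
    "FLAGELLUM_PLUS_MINOR",
    "MAJOR_AXIS",
    "MEASUREMENT_KINDS",
    "MeasurementError",
    "InsufficientDataError",
    "GyreMeasurement",
    "CellRecord",
    "GyreGeometry",
    "CellVolumeResult",
    "minor_axis_diameter",
    "ellipse_cross_section_area",
    "flagellum_circumference",
    "helical_segment_length",
    "gyre_intervals",
    "assemble_gyre_geometries",
    "gyre_volume",
    "estimate_missing_gyre_count",
    "cell_volume",
]

FLAGELLUM_WIDTH = "flagellum_width"
FLAGELLUM_PLUS_MINOR = "flagellum_plus_minor"
MAJOR_AXIS = "major_axis"
MEASUREMENT_KINDS = (FLAGELLUM_WIDTH, FLAGELLUM_PLUS_MINOR, MAJOR_AXIS)


class MeasurementError(ValueError):
    """An internally inconsistent measurement (e.g. max width < min width)."""


class InsufficientDataError(ValueError):
    """Too little usable data to carry out a geometric computation."""


@dataclass(frozen=True)
class GyreMeasurement:
    """One width observation tied to a cell, gyre and half-gyre.

    ``value_um`` is ``None`` when the location was marked but obscured.
    ``center_position_um`` is the longitudinal coordinate of the measurement
    midpoint, micrometres from the head-flagellum junction, increasing
    tailward.
    """

    cell_id: str
    gyre_index: int
    half: int
    kind: str
    value_um: Optional[float]
    center_position_um: Optional[float]
    obscured: bool = False

    def __post_init__(self) -> None:
        if self.kind not in MEASUREMENT_KINDS:
            raise MeasurementError(f"unknown measurement kind {self.kind!r}")
        if self.gyre_index < 1:
            raise MeasurementError(f"gyre_index must be >= 1, got {self.gyre_index}")
        if self.half not in (1, 2):
            raise MeasurementError(f"half must be 1 or 2, got {self.half}")
        if self.value_um is not None and not self.value_um > 0:
            raise MeasurementError(
                f"non-positive width {self.value_um} for {self.cell_id} "
                f"gyre {self.gyre_index} {self.kind}"
            )
        if self.value_um is None and not self.obscured:
            raise MeasurementError(
                f"missing value not flagged obscured ({self.cell_id} "
                f"gyre {self.gyre_index} {self.kind})"
            )


@dataclass
class CellRecord:
    """One sperm cell's measurement series plus segment lengths and metadata."""

    cell_id: str
    species: str
    family: str
    measurements: list[GyreMeasurement] = field(default_factory=list)
    midpiece_length_um: float = 0.0
    tail_length_um: float = 0.0
    nucleus_diameter_um: Optional[float] = None
    obscured_sections_um: list[float] = field(default_factory=list)

    @property
    def flagellum_length_um(self) -> float:
        """Flagellum length = midpiece + tail (exposed flagellum)."""
        return self.midpiece_length_um + self.tail_length_um

    def validate(self) -> None:
        if not self.species:
            raise MeasurementError(f"cell {self.cell_id}: species is empty")
        if not self.flagellum_length_um > 0:
            raise MeasurementError(
                f"cell {self.cell_id}: flagellum length must be positive"
            )
        if any(s < 0 for s in self.obscured_sections_um):
            raise MeasurementError(
                f"cell {self.cell_id}: negative obscured-section length"
            )
        self._validate_measurements()

    def _validate_measurements(self) -> None:
        seen: set[tuple[int, int, str]] = set()
        for m in self.measurements:
            key = (m.gyre_index, m.half, m.kind)
            if key in seen:
                raise MeasurementError(
                    f"cell {self.cell_id}: duplicate measurement "
                    f"(gyre {m.gyre_index}, half {m.half}, {m.kind})"
                )
            seen.add(key)
        # at most one major axis per gyre
        majors: dict[int, int] = {}
        for m in self.measurements:
            if m.kind == MAJOR_AXIS:
                majors[m.gyre_index] = majors.get(m.gyre_index, 0) + 1
        for g, k in majors.items():
            if k > 1:
                raise MeasurementError(
                    f"cell {self.cell_id}: {k} major-axis measures in gyre {g}"
                )
        # max width must dominate min width within a half-gyre
        widths = {
            (m.gyre_index, m.half, m.kind): m.value_um
            for m in self.measurements
            if m.value_um is not None and m.kind != MAJOR_AXIS
        }
        for (g, h, kind), v in widths.items():
            if kind == FLAGELLUM_PLUS_MINOR:
                f = widths.get((g, h, FLAGELLUM_WIDTH))
                if f is not None and v < f:
                    raise MeasurementError(
                        f"cell {self.cell_id}: flagellum+minor {v} < flagellum "
                        f"{f} (gyre {g}, half {h})"
                    )
        # positions must not decrease with gyre index
        pos_by_gyre: dict[int, list[float]] = {}
        for m in self.measurements:
            if m.center_position_um is not None:
                pos_by_gyre.setdefault(m.gyre_index, []).append(m.center_position_um)
        idx = sorted(pos_by_gyre)
        for g0, g1 in zip(idx, idx[1:]):
            if fmean(pos_by_gyre[g1]) < fmean(pos_by_gyre[g0]):
                raise MeasurementError(
                    f"cell {self.cell_id}: positions decrease from gyre {g0} "
                    f"to gyre {g1}"
                )


@dataclass
class GyreGeometry:
    """Per-gyre summary geometry, possibly with cell-mean imputed components."""

    gyre_index: int
    gyre_interval_um: float
    mean_flagellum_diameter_um: float
    mean_minor_axis_um: float
    major_axis_um: float
    imputed_fields: set[str] = field(default_factory=set)


@dataclass
class CellVolumeResult:
    cell_id: str
    per_gyre_volumes_um3: list[float]
    n_measured_gyres: int
    n_estimated_missing_gyres: int
    total_volume_um3: float


def minor_axis_diameter(flag_plus_minor_um: float, flagellum_um: float) -> float:
    """Helix minor-axis diameter by subtraction of the two width measures."""
    if not flag_plus_minor_um > 0 or not flagellum_um > 0:
        raise MeasurementError("widths must be positive")
    minor = flag_plus_minor_um - flagellum_um
    if minor < 0:
        raise MeasurementError(
            f"inconsistent pair: flagellum+minor ({flag_plus_minor_um}) < "
            f"flagellum ({flagellum_um})"
        )
    return minor


def ellipse_cross_section_area(major_axis_um: float, minor_axis_um: float) -> float:
    """Elliptical cross-section area, pi * (major/2) * (minor/2)."""
    if major_axis_um < 0 or minor_axis_um < 0:
        raise MeasurementError("axes must be non-negative")
    return math.pi * (major_axis_um / 2.0) * (minor_axis_um / 2.0)


def flagellum_circumference(mean_diameter_um: float) -> float:
    """Circumference of the flagellum, pi * diameter."""
    if mean_diameter_um < 0:
        raise MeasurementError("diameter must be non-negative")
    return math.pi * mean_diameter_um


def helical_segment_length(gyre_interval_um: float, circumference_um: float) -> float:
    """Length of helix within one gyre: hypotenuse of pitch and circumference.

    Unrolling one turn of a helix of pitch ``g`` wound on a cylinder of
    circumference ``c`` gives a right triangle with legs g and c.
    """
    if gyre_interval_um < 0 or circumference_um < 0:
        raise MeasurementError("inputs must be non-negative")
    return math.hypot(gyre_interval_um, circumference_um)


def gyre_intervals(cell: CellRecord) -> list[tuple[int, float]]:
    """Pitch per consecutive gyre pair, keyed by the leading gyre index.

    The interval between gyres g and g+1 is the difference of the
    ``center_position_um`` of corresponding measurements (same kind, same
    half); when several correspondences exist their mean is used, and when
    none exists the difference of mean gyre positions is used.  Gyres whose
    recorded indices are not adjacent (a fully obscured stretch lies between)
    contribute no interval.
    """
    by_gyre: dict[int, list[GyreMeasurement]] = {}
    for m in cell.measurements:
        if m.center_position_um is not None:
            by_gyre.setdefault(m.gyre_index, []).append(m)
    idx = sorted(by_gyre)
    if len(idx) < 2:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: insufficient gyres ({len(idx)}) to form intervals"
        )
    out: list[tuple[int, float]] = []
    for g0, g1 in zip(idx, idx[1:]):
        if g1 - g0 != 1:
            continue
        a = {(m.kind, m.half): m.center_position_um for m in by_gyre[g0]}
        b = {(m.kind, m.half): m.center_position_um for m in by_gyre[g1]}
        diffs = [b[k] - a[k] for k in a if k in b]
        if diffs:
            iv = fmean(diffs)
        else:
            iv = fmean(b.values()) - fmean(a.values())
        if iv <= 0:
            raise MeasurementError(
                f"cell {cell.cell_id}: non-positive interval between gyres "
                f"{g0} and {g1}"
            )
        out.append((g0, iv))
    if not out:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: no adjacent gyre pairs with positions"
        )
    return out


_COMPONENT_FIELDS = (
    "mean_flagellum_diameter_um",
    "mean_minor_axis_um",
    "major_axis_um",
)


def assemble_gyre_geometries(
    cell: CellRecord, *, last_interval: str = "previous"
) -> list[GyreGeometry]:
    """Per-gyre geometry with cell-mean imputation of missing components.

    ``last_interval`` controls the terminal gyre (and any gyre missing a
    forward interval): ``"previous"`` reuses the preceding gyre's interval,
    ``"cell_mean"`` uses the mean interval of the cell.  Cell means used for
    imputation are computed from directly measured values only.
    """
    if last_interval not in ("previous", "cell_mean"):
        raise ValueError(f"unknown last_interval rule {last_interval!r}")
    cell._validate_measurements()
    by_gyre: dict[int, list[GyreMeasurement]] = {}
    for m in cell.measurements:
        by_gyre.setdefault(m.gyre_index, []).append(m)
    idx = sorted(by_gyre)
    if not idx:
        raise InsufficientDataError(f"cell {cell.cell_id}: no measurements")

    # raw per-gyre component values (None where unmeasured)
    raw: dict[int, dict[str, Optional[float]]] = {}
    for g in idx:
        ms = {(m.kind, m.half): m for m in by_gyre[g]}
        flags = [
            m.value_um
            for (kind, _), m in ms.items()
            if kind == FLAGELLUM_WIDTH and m.value_um is not None
        ]
        minors = []
        for h in (1, 2):
            f = ms.get((FLAGELLUM_WIDTH, h))
            pm = ms.get((FLAGELLUM_PLUS_MINOR, h))
            if f and pm and f.value_um is not None and pm.value_um is not None:
                minors.append(minor_axis_diameter(pm.value_um, f.value_um))
        majors = [
            m.value_um
            for (kind, _), m in ms.items()
            if kind == MAJOR_AXIS and m.value_um is not None
        ]
        raw[g] = {
            "mean_flagellum_diameter_um": fmean(flags) if flags else None,
            "mean_minor_axis_um": fmean(minors) if minors else None,
            "major_axis_um": fmean(majors) if majors else None,
        }

    cell_means: dict[str, float] = {}
    for f_name in _COMPONENT_FIELDS:
        vals = [raw[g][f_name] for g in idx if raw[g][f_name] is not None]
        if not vals:
            raise InsufficientDataError(
                f"cell {cell.cell_id}: cannot impute, no {f_name} measured anywhere"
            )
        cell_means[f_name] = fmean(vals)

    intervals = dict(gyre_intervals(cell))
    mean_interval = fmean(intervals.values())

    geoms: list[GyreGeometry] = []
    prev_iv: Optional[float] = None
    for g in idx:
        if g in intervals:
            iv = intervals[g]
        elif last_interval == "previous" and prev_iv is not None:
            iv = prev_iv
        else:
            iv = mean_interval
        prev_iv = iv
        imputed = {f_name for f_name in _COMPONENT_FIELDS if raw[g][f_name] is None}
        geoms.append(
            GyreGeometry(
                gyre_index=g,
                gyre_interval_um=iv,
                mean_flagellum_diameter_um=raw[g]["mean_flagellum_diameter_um"]
                if raw[g]["mean_flagellum_diameter_um"] is not None
                else cell_means["mean_flagellum_diameter_um"],
                mean_minor_axis_um=raw[g]["mean_minor_axis_um"]
                if raw[g]["mean_minor_axis_um"] is not None
                else cell_means["mean_minor_axis_um"],
                major_axis_um=raw[g]["major_axis_um"]
                if raw[g]["major_axis_um"] is not None
                else cell_means["major_axis_um"],
                imputed_fields=imputed,
            )
        )
    return geoms


def gyre_volume(g: GyreGeometry) -> float:
    """Volume of the helix within one gyre (cross-section area x path length)."""
    area = ellipse_cross_section_area(g.major_axis_um, g.mean_minor_axis_um)
    circ = flagellum_circumference(g.mean_flagellum_diameter_um)
    return area * helical_segment_length(g.gyre_interval_um, circ)


def estimate_missing_gyre_count(
    obscured_length_um: float, mean_gyre_interval_um: float
) -> int:
    """Number of gyres hidden in an obscured stretch (nearest int, half-up)."""
    if obscured_length_um < 0:
        raise MeasurementError("obscured length must be non-negative")
    if not mean_gyre_interval_um > 0:
        raise MeasurementError("mean gyre interval must be positive")
    return max(0, math.floor(obscured_length_um / mean_gyre_interval_um + 0.5))


def cell_volume(cell: CellRecord, *, last_interval: str = "previous") -> CellVolumeResult:
    """Total mitochondrial-helix volume of a cell.

    Sums per-gyre volumes over measured gyres, then adds the mean per-gyre
    volume once for each gyre estimated to be hidden in fully obscured
    sections.
    """
    geoms = assemble_gyre_geometries(cell, last_interval=last_interval)
    vols = [gyre_volume(g) for g in geoms]
    mean_vol = fmean(vols)
    mean_interval = fmean(iv for _, iv in gyre_intervals(cell))
    n_missing = sum(
        estimate_missing_gyre_count(s, mean_interval)
        for s in cell.obscured_sections_um
    )
    return CellVolumeResult(
        cell_id=cell.cell_id,
        per_gyre_volumes_um3=vols,
        n_measured_gyres=len(vols),
        n_estimated_missing_gyres=n_missing,
        total_volume_um3=sum(vols) + n_missing * mean_vol,
    )
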