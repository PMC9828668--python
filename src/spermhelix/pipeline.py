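"""Analysis stages: tapering, gyre interval, allometry, volume, diameters.

Each stage mirrors one model family of the comparative analysis:

* ``stage_allometry`` — log-log PGLS of midpiece length on flagellum length
  from light-microscopy species means, with an outlier-exclusion rerun;
* ``stage_tapering`` — phylogenetic mixed models of a width measure against
  rank-based longitudinal position (0 at the first measured gyre, 1 at the
  last) and mean-centred flagellum length divided by 100, with a
  length x position interaction kept only if significant, plus
  proximal/distal 25% submodels for the flagellum diameter;
* ``stage_gyre_interval`` — same structure for the natural-log gyre interval;
* ``stage_volume`` — PGLS of estimated helix volume on SEM midpiece length,
  with a rerun excluding the family whose fibrous helix inflates the
  estimate (Turdidae);
* ``stage_tail_diameter`` — two-predictor PGLS of the flagellum diameter at
  the start of the tail on light-microscopy tail and midpiece lengths;
* ``stage_nucleus`` — PGLS of the mean of the first three flagellum
  diameters on nucleus diameter.

``run_all`` orchestrates all stages over the four input files and writes a
tidy coefficient report (term, estimate, CI, p, lambda) per stage.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    FLAGELLUM_PLUS_MINOR,
    FLAGELLUM_WIDTH,
    MAJOR_AXIS,
    CellRecord,
    InsufficientDataError,
    cell_volume,
    gyre_intervals,
    minor_axis_diameter,
)
from .io import RunConfig, normalize_species
from .phylostats import (
    ModelFit,
    PhyloCovariance,
    drop_nonsignificant_interaction,
    fit_pgls,
    fit_phylo_lmm,
    phylo_covariance,
)

__all__ = [
    "LongitudinalObservation",
    "StageReport",
    "RESPONSE_KINDS",
    "longitudinal_positions",
    "longitudinal_observations",
    "proximal_distal_subsets",
    "residual_normality_improves",
    "stage_allometry",
    "stage_tapering",
    "stage_gyre_interval",
    "stage_volume",
    "stage_tail_diameter",
    "stage_nucleus",
    "run_all",
    "report_frame",
]

RESPONSE_KINDS = (
    "flagellum_diameter",
    "minor_axis",
    "major_axis",
    "gyre_interval",
)


@dataclass(frozen=True)
class LongitudinalObservation:
    """One response value at a rank-based longitudinal position."""

    cell_id: str
    species: str
    kind: str
    value: float
    position01: float
    flagellum_length_um: float


@dataclass
class StageReport:
    stage: str
    fits: dict[str, ModelFit]
    subset: dict[str, str] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


def _rank_positions(locations: Sequence[float]) -> np.ndarray:
    """(rank - 1)/(n - 1) over ordered measurement locations."""
    n = len(locations)
    if n < 2:
        raise InsufficientDataError("single measured location")
    order = np.argsort(np.argsort(locations, kind="stable"), kind="stable")
    return order / (n - 1)


def longitudinal_positions(cell: CellRecord, kind: str = FLAGELLUM_WIDTH) -> np.ndarray:
    """Proportional positions of a cell's measured locations of one kind."""
    locs = [
        m.center_position_um
        for m in cell.measurements
        if m.kind == kind and m.value_um is not None and m.center_position_um is not None
    ]
    return _rank_positions(locs)


def _cell_observations(cell: CellRecord, kind: str) -> list[tuple[float, float]]:
    """(location, value) pairs for one response kind."""
    if kind == "flagellum_diameter":
        return sorted(
            (m.center_position_um, m.value_um)
            for m in cell.measurements
            if m.kind == FLAGELLUM_WIDTH
            and m.value_um is not None
            and m.center_position_um is not None
        )
    if kind == "minor_axis":
        flags = {
            (m.gyre_index, m.half): m
            for m in cell.measurements
            if m.kind == FLAGELLUM_WIDTH and m.value_um is not None
        }
        out = []
        for m in cell.measurements:
            if m.kind != FLAGELLUM_PLUS_MINOR or m.value_um is None:
                continue
            f = flags.get((m.gyre_index, m.half))
            if f is None or f.center_position_um is None:
                continue
            minor = minor_axis_diameter(m.value_um, f.value_um)
            if minor > 0:
                out.append((f.center_position_um, minor))
        return sorted(out)
    if kind == "major_axis":
        return sorted(
            (m.center_position_um, m.value_um)
            for m in cell.measurements
            if m.kind == MAJOR_AXIS
            and m.value_um is not None
            and m.center_position_um is not None
        )
    if kind == "gyre_interval":
        try:
            ivs = gyre_intervals(cell)
        except InsufficientDataError:
            return []
        return [(float(g), iv) for g, iv in ivs]
    raise ValueError(f"unknown response kind {kind!r}")


def longitudinal_observations(
    cells: Sequence[CellRecord], kind: str
) -> pd.DataFrame:
    """Observation table for one response kind across cells.

    Cells with fewer than two measured locations are excluded with a
    warning.  ``position01`` is rank-based within each cell.
    """
    rows = []
    for cell in cells:
        pairs = _cell_observations(cell, kind)
        if len(pairs) < 2:
            warnings.warn(
                f"cell {cell.cell_id}: fewer than 2 {kind} locations; excluded"
            )
            continue
        pos = _rank_positions([p for p, _ in pairs])
        for p01, (_, v) in zip(pos, pairs):
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "species": cell.species,
                    "kind": kind,
                    "value": v,
                    "position01": float(p01),
                    "flagellum_um": cell.flagellum_length_um,
                }
            )
    if not rows:
        raise InsufficientDataError(f"no usable observations for {kind}")
    return pd.DataFrame(rows)


def _scaled_length(obs: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Mean-centred (over cells) flagellum length divided by 100."""
    per_cell = obs.drop_duplicates("cell_id")["flagellum_um"]
    grand = float(per_cell.mean())
    return (obs["flagellum_um"].to_numpy() - grand) / 100.0, grand


def proximal_distal_subsets(
    obs: pd.DataFrame, fraction: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell head-end and tail-end observation windows (ceiling rule)."""
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    prox, dist = [], []
    for _, sub in obs.groupby("cell_id", sort=False):
        sub = sub.sort_values("position01", kind="stable")
        k = math.ceil(fraction * len(sub))
        if k == 0:
            raise InsufficientDataError("empty subset")
        prox.append(sub.iloc[:k])
        dist.append(sub.iloc[-k:])
    return (
        pd.concat(prox, ignore_index=True),
        pd.concat(dist, ignore_index=True),
    )


def _shapiro_w(resid: np.ndarray) -> float:
    r = np.asarray(resid, dtype=float)
    if len(r) > 4999:  # scipy's shapiro limit; deterministic thinning
        step = math.ceil(len(r) / 4999)
        r = r[::step]
    return float(stats.shapiro(r).statistic)


def residual_normality_improves(
    y: np.ndarray,
    X: np.ndarray,
    species: Sequence[str],
    C: PhyloCovariance,
) -> tuple[bool, dict]:
    """Whether log-transforming the response improves residual normality.

    Fits the model on the raw and log scales and compares the Shapiro-Wilk
    statistic of the conditional residuals; log wins iff its W is larger.
    Non-positive responses force the raw scale.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        warnings.warn("non-positive response; log transform not considered")
        return False, {"reason": "non-positive response"}
    fit_raw = fit_phylo_lmm(X, y, species, C, compute_p=False)
    fit_log = fit_phylo_lmm(X, np.log(y), species, C, compute_p=False)
    w_raw = _shapiro_w(fit_raw.residuals)
    w_log = _shapiro_w(fit_log.residuals)
    return bool(w_log > w_raw), {"shapiro_raw": w_raw, "shapiro_log": w_log}


def _prune_cov(tree, species: Sequence[str]) -> PhyloCovariance:
    """Covariance restricted to the species actually present."""
    pc = phylo_covariance(tree)
    want = [normalize_species(s) for s in dict.fromkeys(species)]
    missing = sorted(set(want) - set(pc.species_order))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    return pc.subset(want)


def _tapering_design(
    obs: pd.DataFrame, *, interaction: bool
) -> tuple[np.ndarray, list[str], float]:
    ls, grand = _scaled_length(obs)
    p01 = obs["position01"].to_numpy()
    cols = [np.ones(len(obs)), p01, ls]
    names = ["intercept", "position", "flagellum_length"]
    if interaction:
        cols.append(ls * p01)
        names.append("length_x_position")
    return np.column_stack(cols), names, grand


def stage_tapering(
    cells: Sequence[CellRecord],
    tree,
    response_kind: str = "flagellum_diameter",
    *,
    alpha: float = 0.05,
    transform: str = "auto",
    subset_fraction: Optional[float] = 0.25,
    compute_p: bool = True,
) -> StageReport:
    """Longitudinal model of one width measure, Table-style.

    Full model: response ~ position01 + scaled flagellum length
    (+ interaction, removed if nonsignificant), species random effect with
    phylogenetic covariance.  For the flagellum diameter,
    proximal/distal windows are refit with flagellum length only.
    """
    if response_kind not in RESPONSE_KINDS:
        raise ValueError(f"unknown response kind {response_kind!r}")
    obs = longitudinal_observations(cells, response_kind)
    C = _prune_cov(tree, obs["species"])
    species = [normalize_species(s) for s in obs["species"]]
    y_raw = obs["value"].to_numpy(dtype=float)

    X_full, names_full, grand = _tapering_design(obs, interaction=True)
    if transform == "auto":
        use_log, norm_notes = residual_normality_improves(y_raw, X_full, species, C)
    elif transform in ("raw", "log"):
        use_log, norm_notes = transform == "log", {"forced": transform}
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if use_log and np.any(y_raw <= 0):
        warnings.warn("non-positive response; falling back to raw scale")
        use_log = False
    y = np.log(y_raw) if use_log else y_raw

    X_red, names_red, _ = _tapering_design(obs, interaction=False)
    fit_full = fit_phylo_lmm(X_full, y, species, C, names_full, compute_p=False)
    fit_red = fit_phylo_lmm(X_red, y, species, C, names_red, compute_p=False)
    chosen, p_int = drop_nonsignificant_interaction(fit_full, fit_red, alpha)
    X_fin, names_fin = (
        (X_full, names_full) if chosen is fit_full else (X_red, names_red)
    )
    final = fit_phylo_lmm(X_fin, y, species, C, names_fin, compute_p=compute_p)
    final.transform_applied = use_log
    final.notes.update(chosen.notes)

    fits = {"main": final}
    notes = {
        "response": response_kind,
        "log_transformed": use_log,
        "interaction_p": p_int,
        "interaction_kept": chosen is fit_full,
        "grand_mean_flagellum_um": grand,
        **norm_notes,
    }
    if subset_fraction is not None and response_kind == "flagellum_diameter":
        prox, dist = proximal_distal_subsets(obs, subset_fraction)
        for label, sub in (("proximal", prox), ("distal", dist)):
            ls_s = (sub["flagellum_um"].to_numpy() - grand) / 100.0
            Xs = np.column_stack([np.ones(len(sub)), ls_s])
            ys = (
                np.log(sub["value"].to_numpy(dtype=float))
                if use_log
                else sub["value"].to_numpy(dtype=float)
            )
            sp_s = [normalize_species(s) for s in sub["species"]]
            fsub = fit_phylo_lmm(
                Xs, ys, sp_s, C.subset(list(dict.fromkeys(sp_s))),
                ["intercept", "flagellum_length"], compute_p=compute_p,
            )
            fsub.transform_applied = use_log
            fits[f"{label}_{int(round(subset_fraction * 100))}"] = fsub
    return StageReport(
        stage=f"tapering[{response_kind}]",
        fits=fits,
        subset={"fraction": str(subset_fraction)},
        notes=notes,
    )


def stage_gyre_interval(
    cells: Sequence[CellRecord],
    tree,
    *,
    alpha: float = 0.05,
    compute_p: bool = True,
) -> StageReport:
    """Log gyre interval against position and flagellum length."""
    report = stage_tapering(
        cells,
        tree,
        "gyre_interval",
        alpha=alpha,
        transform="log",
        subset_fraction=None,
        compute_p=compute_p,
    )
    report.stage = "gyre_interval"
    return report


def stage_allometry(
    species_table: pd.DataFrame,
    tree,
    exclude: Optional[Sequence[str]] = None,
    *,
    compute_p: bool = True,
) -> StageReport:
    """Log-log PGLS of midpiece on flagellum length (light microscopy means).

    ``exclude=None`` reruns without the species with the shortest midpiece
    (the residual outlier); an explicit list reruns without those species;
    an empty list skips the rerun arm (both fits identical).
    """
    df = species_table.copy()
    df["species"] = df["species"].map(normalize_species)
    df = df.reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("need at least 3 species")
    df["flagellum_um"] = df["midpiece_um"] + df["tail_um"]
    C = _prune_cov(tree, df["species"])

    def _fit(sub: pd.DataFrame) -> ModelFit:
        Csub = C.subset(list(sub["species"]))
        X = np.column_stack(
            [np.ones(len(sub)), np.log(sub["flagellum_um"].to_numpy())]
        )
        y = np.log(sub["midpiece_um"].to_numpy())
        fit = fit_pgls(
            X, y, Csub, ["intercept", "log_flagellum_length"], compute_p=compute_p
        )
        fit.transform_applied = True
        return fit

    fit_all = _fit(df)
    if exclude is None:
        exclude = [df.loc[df["midpiece_um"].idxmin(), "species"]]
    exclude = [normalize_species(s) for s in exclude]
    sub = df[~df["species"].isin(exclude)].reset_index(drop=True)
    fit_ex = _fit(sub) if len(sub) < len(df) else fit_all
    return StageReport(
        stage="allometry",
        fits={"all": fit_all, "excluded": fit_ex},
        subset={"excluded_species": ",".join(exclude) if len(sub) < len(df) else ""},
        notes={"n_all": len(df), "n_excluded_fit": len(sub)},
    )


def stage_volume(
    cells: Sequence[CellRecord],
    tree,
    *,
    excluded_family: str = "Turdidae",
    compute_p: bool = True,
) -> tuple[StageReport, pd.DataFrame]:
    """PGLS of estimated helix volume on SEM midpiece length.

    Returns the report and the per-cell volume table.  The rerun excludes
    ``excluded_family`` (whose extra fibrous helix biases the estimate).
    """
    rows = []
    for cell in cells:
        try:
            res = cell_volume(cell)
        except InsufficientDataError as exc:
            warnings.warn(f"cell {cell.cell_id}: no volume ({exc})")
            continue
        rows.append(
            {
                "cell_id": cell.cell_id,
                "species": normalize_species(cell.species),
                "family": cell.family,
                "midpiece_um": cell.midpiece_length_um,
                "n_measured_gyres": res.n_measured_gyres,
                "n_estimated_missing_gyres": res.n_estimated_missing_gyres,
                "volume_um3": res.total_volume_um3,
            }
        )
    vt = pd.DataFrame(rows)
    if len(vt) < 3:
        raise InsufficientDataError("fewer than 3 cells with volumes")
    C = _prune_cov(tree, vt["species"])

    def _fit(sub: pd.DataFrame) -> ModelFit:
        Csub = C.subset(list(sub["species"]))
        X = np.column_stack([np.ones(len(sub)), sub["midpiece_um"].to_numpy()])
        if np.var(sub["midpiece_um"].to_numpy()) == 0:
            raise np.linalg.LinAlgError("zero-variance midpiece lengths")
        return fit_pgls(
            X,
            sub["volume_um3"].to_numpy(),
            Csub,
            ["intercept", "midpiece_length"],
            compute_p=compute_p,
        )

    fit_all = _fit(vt)
    sub = vt[vt["family"] != excluded_family].reset_index(drop=True)
    fit_ex = _fit(sub) if 3 <= len(sub) < len(vt) else fit_all
    report = StageReport(
        stage="volume",
        fits={"all": fit_all, "family_excluded": fit_ex},
        subset={"excluded_family": excluded_family if len(sub) < len(vt) else ""},
        notes={"n_cells": len(vt), "n_without_family": len(sub)},
    )
    return report, vt


def _tail_start_diameter(cell: CellRecord) -> Optional[float]:
    """Most distal measured flagellum width (at the midpiece end)."""
    ms = [
        m
        for m in cell.measurements
        if m.kind == FLAGELLUM_WIDTH
        and m.value_um is not None
        and m.center_position_um is not None
    ]
    if not ms:
        return None
    return max(ms, key=lambda m: m.center_position_um).value_um


def stage_tail_diameter(
    cells: Sequence[CellRecord],
    species_table: pd.DataFrame,
    tree,
    *,
    compute_p: bool = True,
) -> StageReport:
    """Tail-start flagellum diameter vs light-microscopy tail and midpiece.

    Both predictors enter one PGLS; a variance-inflation diagnostic guards
    against their collinearity (tail and midpiece both scale with total
    length).
    """
    st = species_table.copy()
    st["species"] = st["species"].map(normalize_species)
    lm = st.set_index("species")
    rows = []
    for cell in cells:
        d = _tail_start_diameter(cell)
        sp = normalize_species(cell.species)
        if d is None:
            warnings.warn(f"cell {cell.cell_id}: no tail-start diameter")
            continue
        if sp not in lm.index:
            raise ValueError(f"species {sp} missing from light-microscopy table")
        rows.append(
            {
                "species": sp,
                "diameter_um": d,
                "tail_um": float(lm.loc[sp, "tail_um"]),
                "midpiece_um": float(lm.loc[sp, "midpiece_um"]),
            }
        )
    df = pd.DataFrame(rows)
    C = _prune_cov(tree, df["species"])
    X = np.column_stack(
        [np.ones(len(df)), df["tail_um"].to_numpy(), df["midpiece_um"].to_numpy()]
    )
    names = ["intercept", "tail_length", "midpiece_length"]
    vif = _max_vif(X[:, 1:])
    if not np.isfinite(vif):
        raise np.linalg.LinAlgError("perfectly collinear predictors")
    if vif > 10:
        warnings.warn(f"high collinearity between predictors (VIF {vif:.1f})")
    fit = fit_pgls(X, df["diameter_um"].to_numpy(), C, names, compute_p=compute_p)
    return StageReport(
        stage="tail_diameter",
        fits={"main": fit},
        notes={
            "max_vif": vif,
            "mean_diameter_um": float(df["diameter_um"].mean()),
            "sd_diameter_um": float(df["diameter_um"].std(ddof=1)),
        },
    )


def _max_vif(P: np.ndarray) -> float:
    out = 0.0
    for j in range(P.shape[1]):
        others = np.column_stack(
            [np.ones(len(P))] + [P[:, k] for k in range(P.shape[1]) if k != j]
        )
        pred, *_ = np.linalg.lstsq(others, P[:, j], rcond=None)
        resid = P[:, j] - others @ pred
        tss = float(np.sum((P[:, j] - P[:, j].mean()) ** 2))
        rss = float(np.sum(resid**2))
        if rss <= 1e-12 * max(tss, 1.0):
            return float("inf")
        out = max(out, tss / rss)
    return out


def stage_nucleus(
    cells: Sequence[CellRecord], tree, *, compute_p: bool = True
) -> StageReport:
    """Neck-region flagellum diameter (mean of first three) vs nucleus."""
    rows = []
    for cell in cells:
        ms = sorted(
            (
                (m.center_position_um, m.value_um)
                for m in cell.measurements
                if m.kind == FLAGELLUM_WIDTH
                and m.value_um is not None
                and m.center_position_um is not None
            )
        )
        if len(ms) < 3 or cell.nucleus_diameter_um is None:
            warnings.warn(f"cell {cell.cell_id}: excluded from nucleus model")
            continue
        rows.append(
            {
                "species": normalize_species(cell.species),
                "neck_diameter_um": fmean(v for _, v in ms[:3]),
                "nucleus_um": cell.nucleus_diameter_um,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) < 3:
        raise InsufficientDataError("fewer than 3 cells for the nucleus model")
    C = _prune_cov(tree, df["species"])
    X = np.column_stack([np.ones(len(df)), df["nucleus_um"].to_numpy()])
    if np.var(df["nucleus_um"].to_numpy()) == 0:
        raise np.linalg.LinAlgError("constant nucleus diameter")
    fit = fit_pgls(
        X,
        df["neck_diameter_um"].to_numpy(),
        C,
        ["intercept", "nucleus_diameter"],
        compute_p=compute_p,
    )
    return StageReport(stage="nucleus", fits={"main": fit})


def report_frame(reports: Sequence[StageReport]) -> pd.DataFrame:
    """Tidy coefficient table across stages (Table-style columns)."""
    rows = []
    for rep in reports:
        for fit_name, fit in rep.fits.items():
            for term in fit.terms:
                lo, hi = fit.ci95[term]
                lam_lo, lam_hi = fit.lambda_ci or (float("nan"), float("nan"))
                rows.append(
                    {
                        "stage": rep.stage,
                        "fit": fit_name,
                        "term": term,
                        "estimate": fit.coefficients[term],
                        "ci_low": lo,
                        "ci_high": hi,
                        "p": fit.p_values.get(term, float("nan")),
                        "lambda": fit.lambda_,
                        "lambda_low": lam_lo,
                        "lambda_high": lam_hi,
                        "log_transformed": fit.transform_applied,
                        "n_obs": fit.n_obs,
                        "n_species": fit.n_species,
                    }
                )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute geometry and every configured stage; write the report bundle."""
    from . import io as shio
    from . import __version__

    for attr in ("measurements", "cells", "species", "tree"):
        path = Path(getattr(config, attr))
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
    import time
    from datetime import datetime, timezone

    log_lines: list[str] = []

    def _log(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    t_start = time.time()
    cells = shio.read_cell_records(config.measurements, config.cells)
    species_table = shio.read_species(config.species)
    tree = shio.read_tree(
        config.tree, species=[c.species for c in cells]
    )
    _log(
        f"loaded {len(cells)} cells, {len(species_table)} species rows, "
        f"{len(list(tree.leaf_node_iter()))} tree tips"
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reports: list[StageReport] = []
    volume_table = None
    stage_set = set(config.stages)
    if "allometry" in stage_set:
        reports.append(
            stage_allometry(
                species_table, tree,
                exclude=config.exclusions if config.exclusions else None,
            )
        )
    if "tapering" in stage_set:
        for kind in ("flagellum_diameter", "minor_axis", "major_axis"):
            reports.append(
                stage_tapering(
                    cells, tree, kind,
                    alpha=config.alpha,
                    subset_fraction=config.subset_fraction,
                )
            )
    if "gyre_interval" in stage_set:
        reports.append(stage_gyre_interval(cells, tree, alpha=config.alpha))
    if "volume" in stage_set:
        rep, volume_table = stage_volume(
            cells, tree, excluded_family=config.excluded_family
        )
        reports.append(rep)
    if "tail_diameter" in stage_set:
        reports.append(stage_tail_diameter(cells, species_table, tree))
    if "nucleus" in stage_set:
        reports.append(stage_nucleus(cells, tree))

    for rep in reports:
        _log(f"stage {rep.stage}: {len(rep.fits)} fits")
    frame = report_frame(reports)
    frame.to_csv(out / "model_report.csv", index=False)
    if volume_table is not None:
        volume_table.to_csv(out / "volumes.csv", index=False)
    manifest = {
        "package": "spermhelix",
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": sorted(stage_set),
        "n_cells": len(cells),
        "lambda_definition": (
            "PGLS: Pagel's lambda by profiled ML; LMM: phylogenetic variance "
            "proportion sigma_a^2*h/(sigma_a^2*h + sigma_e^2)"
        ),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _log(f"done in {time.time() - t_start:.2f}s")
    # timestamps live only here; the report files stay byte-deterministic
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {"reports": reports, "volumes": volume_table, "out_dir": str(out)}
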