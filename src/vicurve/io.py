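"""CSV formats, run configuration, and end-to-end pipeline orchestration.

The contract surface is tidy CSV: VA input as
``patient_id,distance_cm,va_letters``, questionnaire scores as
``patient_id,total_score,near_activities,distance_activities[,complete]``,
item-level responses as ``patient_id,item_id,response``. All files are
comma-separated UTF-8 with a header row and period decimal separator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import curves, scoring, stats
from .cohort import Cohort
from .errors import PipelineError, VicurveError
from .profiles import ALL_SUBSETS, DISTANCES_9, NEAR_SPLIT_CM
from .simulate import SimParams, simulate_cohort

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one input source: either ``sim`` (synthetic cohort parameters)
    or file paths (``va_csv`` plus ``qol_csv`` or ``items_csv``).
    """

    model_config = ConfigDict(frozen=True)

    sim: Optional[SimParams] = None
    va_csv: Optional[str] = None
    qol_csv: Optional[str] = None
    items_csv: Optional[str] = None

    subsets: Tuple[str, ...] = ALL_SUBSETS
    split_cm: float = NEAR_SPLIT_CM
    x_axis: str = "cm"
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    holm: bool = False
    seed: Optional[int] = None  # overrides sim.seed when given
    out_dir: str = "vicurve_out"
    plots: bool = False

    @model_validator(mode="after")
    def _one_source(self):
        file_input = self.va_csv is not None
        if self.sim is not None and file_input:
            raise ValueError("sim: give either simulation parameters or input paths, not both")
        if self.sim is None and not file_input:
            raise ValueError("va_csv: either sim parameters or a VA input path is required")
        if file_input and self.qol_csv is None and self.items_csv is None:
            raise ValueError("qol_csv: file input needs qol_csv (scores) or items_csv (responses)")
        if not (25.0 < self.split_cm < 300.0):
            raise ValueError("split_cm: must lie strictly inside [25, 300] cm")
        if self.x_axis not in ("cm", "diopters"):
            raise ValueError("x_axis: must be 'cm' or 'diopters'")
        unknown = [s for s in self.subsets if s not in ALL_SUBSETS]
        if unknown:
            raise ValueError(f"subsets: unknown subset ids {unknown}")
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# --------------------------------------------------------------------------
# readers / writers

def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise VicurveError(f"cannot read CSV {path}: {exc}") from exc


def read_va_csv(path, grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Read and validate a long-format VA table.

    Checks column names, numeric parsability (reported with 1-based data
    line numbers, header = line 1), the [0, 100] Letters range, positive
    distances, duplicate (patient, distance) pairs, and optionally that
    every distance belongs to the configured grid.
    """
    df = _read_csv(path)
    required = ["patient_id", "distance_cm", "va_letters"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VicurveError(f"{path}: missing column(s) {missing}")
    lines = df.index + 2  # header is line 1
    for col in ("distance_cm", "va_letters"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise VicurveError(
                f"{path}: malformed {col} value(s) at line(s) "
                f"{[int(lines[i]) for i in bad[:5]]}"
            )
        df[col] = vals
    bad = df.index[(df["va_letters"] < 0) | (df["va_letters"] > 100)]
    if len(bad):
        raise VicurveError(
            f"{path}: VA outside [0, 100] Letters at line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"
        )
    bad = df.index[df["distance_cm"] <= 0]
    if len(bad):
        raise VicurveError(
            f"{path}: non-positive distance at line(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    dup = df.duplicated(subset=["patient_id", "distance_cm"], keep="first")
    if dup.any():
        raise VicurveError(
            f"{path}: duplicate (patient_id, distance_cm) pair(s) at line(s) "
            f"{[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    if grid is not None:
        allowed = set(float(g) for g in grid)
        bad = df.index[~df["distance_cm"].astype(float).isin(allowed)]
        if len(bad):
            raise VicurveError(
                f"{path}: distance not on the configured grid at line(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
    df["patient_id"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)


def read_qol_csv(path) -> pd.DataFrame:
    """Read a score-level questionnaire table (0-100 scores)."""
    df = _read_csv(path)
    required = ["patient_id", "total_score", "near_activities", "distance_activities"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VicurveError(f"{path}: missing column(s) {missing}")
    for col in required[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise VicurveError(
                f"{path}: malformed {col} at line(s) {[int(i) + 2 for i in bad[:5]]}"
            )
        if ((vals < 0) | (vals > 100)).any():
            raise VicurveError(f"{path}: {col} outside [0, 100]")
        df[col] = vals
    if "complete" not in df.columns:
        df["complete"] = df[required[1:]].notna().all(axis=1)
    df["complete"] = df["complete"].astype(bool)
    dup = df.duplicated(subset=["patient_id"])
    if dup.any():
        raise VicurveError(
            f"{path}: duplicate patient_id at line(s) {[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    df["patient_id"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)


def read_items_csv(path) -> pd.DataFrame:
    """Read item-level responses and score them to the QoL table."""
    df = _read_csv(path)
    required = ["patient_id", "item_id", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VicurveError(f"{path}: missing column(s) {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return scoring.score_items_frame(df)


# --------------------------------------------------------------------------
# pipeline

@dataclass
class ReportBundle:
    """Everything one pipeline run produces, before writing to disk."""

    cohort: Cohort
    aoc_long: pd.DataFrame
    aoc_wide: pd.DataFrame
    normality: pd.DataFrame
    correlations: pd.DataFrame
    quartiles: pd.DataFrame
    manifest: Dict


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except VicurveError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    return wrap


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Simulate-or-load, score, filter, compute AoC indices, and analyse.

    Stage order: input -> complete-case filter -> per-patient AoC table ->
    correlation battery + normality table + quartile comparison. The
    manifest records the configuration, the seed, and row counts at every
    stage. Any stage failure raises :class:`PipelineError` tagged with the
    stage name.
    """
    manifest: Dict = {"config": json.loads(config.model_dump_json())}

    # --- input
    try:
        if config.sim is not None:
            params = config.sim
            if config.seed is not None:
                params = params.model_copy(update={"seed": config.seed})
            cohort = simulate_cohort(params)
            manifest["seed"] = params.seed
            grid = params.distances_cm
        else:
            va = read_va_csv(config.va_csv, grid=None)
            if config.qol_csv is not None:
                qol = read_qol_csv(config.qol_csv)
            else:
                qol = read_items_csv(config.items_csv)
            cohort = Cohort(va=va, qol=qol, provenance={
                "va_csv": str(config.va_csv),
                "qol_csv": str(config.qol_csv or config.items_csv),
            })
            manifest["seed"] = config.seed
            grid = DISTANCES_9
    except VicurveError as exc:
        raise PipelineError("input", str(exc)) from exc
    manifest["patients_in"] = cohort.n

    # --- complete cases
    try:
        analysed = scoring.filter_complete(cohort, required_distances=grid)
    except VicurveError as exc:
        raise PipelineError("filter_complete", str(exc)) from exc
    manifest["patients_analyzed"] = analysed.n

    # --- AoC indices
    aoc_long = _stage("aoc_table")(
        curves.aoc_table, analysed.profiles(), subsets=config.subsets,
        split_cm=config.split_cm, x_axis=config.x_axis,
    )
    wide = curves.aoc_wide(aoc_long)
    manifest["aoc_rows"] = len(aoc_long)

    # --- statistics
    qol = analysed.qol
    va40 = va300 = None
    va_idx = analysed.va.set_index(["patient_id", "distance_cm"])["va_letters"]
    try:
        va40 = va_idx.xs(40.0, level="distance_cm")
        va300 = va_idx.xs(300.0, level="distance_cm")
    except KeyError:
        logger.info("single-VA rows skipped: 40 or 300 cm not measured")

    correlations = _stage("correlation_battery")(
        stats.correlation_battery, wide, qol, va40=va40, va300=va300,
        alpha=config.alpha, holm=config.holm,
    )

    norm_vars = {name: wide[name] for name in (
        "total_S9", "near_S9", "distance_S9",
        "total_DCT", "near_DCT", "distance_DCT",
    ) if name in wide.columns}
    qidx = qol.set_index("patient_id").loc[wide.index]
    norm_vars["total_score"] = qidx["total_score"]
    norm_vars["near_activities"] = qidx["near_activities"]
    norm_vars["distance_activities"] = qidx["distance_activities"]
    if va40 is not None:
        norm_vars["va_40cm"] = va40.loc[wide.index]
        norm_vars["va_300cm"] = va300.loc[wide.index]
    normality = _stage("normality_table")(stats.normality_table, norm_vars)

    variables = wide.copy()
    if analysed.covariates is not None:
        cov = analysed.covariates.set_index("patient_id").loc[wide.index]
        for c in cov.columns:
            variables[c] = cov[c]
    comparisons = _stage("quartile_compare")(
        stats.quartile_compare, variables, qidx["total_score"], alpha=config.alpha,
    )
    quartiles = stats.comparisons_frame(comparisons)
    manifest["correlation_rows"] = len(correlations)
    manifest["quartile_group_sizes"] = [int(comparisons[0].n_low), int(comparisons[0].n_rest)]

    return ReportBundle(
        cohort=analysed, aoc_long=aoc_long, aoc_wide=wide,
        normality=normality, correlations=correlations,
        quartiles=quartiles, manifest=manifest,
    )


def write_report(bundle: ReportBundle, out_dir, plots: bool = False) -> Dict[str, str]:
    """Write the report bundle as CSV files plus a JSON manifest.

    Returns a name -> path map. With ``plots=True`` also writes the three
    score-versus-AoC scatter panels (total, near, distance) as PNGs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def _write(name: str, df: pd.DataFrame, index=False):
        p = out / f"{name}.csv"
        df.to_csv(p, index=index)
        files[name] = str(p)

    _write("va_profiles", bundle.cohort.va)
    _write("qol_scores", bundle.cohort.qol)
    if bundle.cohort.covariates is not None:
        _write("covariates", bundle.cohort.covariates)
    _write("aoc_indices", bundle.aoc_long)
    _write("aoc_indices_wide", bundle.aoc_wide.reset_index())
    _write("normality", bundle.normality)
    _write("correlations", bundle.correlations)
    _write("quartile_comparison", bundle.quartiles)

    mp = out / "manifest.json"
    with open(mp, "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    files["manifest"] = str(mp)

    if plots:
        files.update(_scatter_panels(bundle, out))
    return files


def _scatter_panels(bundle: ReportBundle, out: Path) -> Dict[str, str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qidx = bundle.cohort.qol.set_index("patient_id").loc[bundle.aoc_wide.index]
    panels = [
        ("scatter_total", "total_S9", "total_score", "Total AoC (Letters*cm)", "NEI-VFQ total"),
        ("scatter_near", "near_S9", "near_activities", "AoCN (Letters*cm)", "Near activities"),
        ("scatter_distance", "distance_S9", "distance_activities",
         "AoCD (Letters*cm)", "Distance activities"),
    ]
    files = {}
    for name, xcol, ycol, xlab, ylab in panels:
        if xcol not in bundle.aoc_wide.columns:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.scatter(bundle.aoc_wide[xcol], qidx[ycol], s=12, alpha=0.7)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        fig.tight_layout()
        p = out / f"{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files[name] = str(p)
    return files
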