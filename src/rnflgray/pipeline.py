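"""End-to-end pipeline: synthesize -> segment -> measure -> analyze.

The pipeline is a pure function of (config, seed): reruns with the same
configuration produce byte-identical output files.  Eyes are excluded,
and accounted for, in this order:

1. ``quality_gate``               - measured scan quality at or below the
                                    usability gate (default 45);
2. ``boundary_misidentification`` - the segmenter found no admissible
                                    boundary, or the automated QC screen
                                    flagged the traced result;
3. ``motion_artifact``            - a manual exclusion flag carried in
                                    the input (this package renders no
                                    motion artifacts; the category
                                    exists so real-world accounting has
                                    a place to live).

The manifest reports recruited = analyzed + sum(excluded) and the run is
aborted if that conservation ever fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortstats
from .errors import SchemaError, SegmentationFailure
from .image import write_image
from .quantify import MEASUREMENT_COLUMNS, compute_imageq, measure_eye
from .segmentation import flag_misidentification, segment_boundaries
from .synthdata import (
    GenerativeParams,
    CovariateSpec,
    cohort_to_frame,
    degrade_quality,
    degrade_rng,
    render_bscan,
    sample_cohort,
)

#: Mandatory columns of a cohort CSV.
MANDATORY_COHORT_COLUMNS = (
    "subject_id", "age", "sex", "se", "bcva", "al", "iop", "vf_md",
)


@dataclass
class PipelineConfig:
    """Everything a full run depends on."""

    n_eyes: int = 397
    seed: int = 0
    params: GenerativeParams = field(default_factory=GenerativeParams)
    out_dir: str | Path | None = None
    save_images: bool = False
    image_height: int = 480
    quality_gate: float = 45.0
    alpha: float = 0.05
    forced_covariates: tuple[str, ...] = ("al",)
    age_edges: tuple[float, ...] = cohortstats.DEFAULT_AGE_EDGES
    motion_artifact_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        from .quality import QCAL_MAX, QCAL_MIN

        if not QCAL_MIN <= self.quality_gate <= QCAL_MAX:
            raise ValueError(
                f"quality gate {self.quality_gate} outside proxy calibration "
                f"range [{QCAL_MIN}, {QCAL_MAX}]"
            )
        if self.seed != self.params.seed:
            self.params = dataclasses.replace(self.params, seed=self.seed)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Top-level keys map to PipelineConfig fields; the ``params`` mapping
    maps to GenerativeParams fields, with ``covariates`` given as
    ``{name: {mean, sd, lo, hi}}``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params_raw = raw.pop("params", {})
    if "covariates" in params_raw:
        # partial overrides merge into the default covariate set
        merged_cov = dict(GenerativeParams().covariates)
        merged_cov.update(
            {k: CovariateSpec(**v) for k, v in params_raw["covariates"].items()}
        )
        params_raw["covariates"] = merged_cov
    for tup_key in ("forced_covariates", "age_edges", "motion_artifact_ids"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    seed = raw.get("seed", 0)
    params = GenerativeParams(seed=seed, **params_raw)
    return PipelineConfig(params=params, **raw)


def process_eye(truth, config: PipelineConfig):
    """Render, degrade, gate, segment, QC and measure one eye.

    Returns (measurement | None, exclusion_reason | None, image, gt).
    """
    params = config.params
    image, gt = render_bscan(
        truth, params, height=config.image_height
    )
    image = degrade_quality(
        image, truth.imageq_true, degrade_rng(params, truth.subject_id)
    )
    # The emulated device exports its quality factor with the scan, as
    # clinical instruments do; the pixel-based proxy backs it up only
    # when no device value accompanies an image.
    image = dataclasses.replace(image, quality_factor=truth.imageq_true)
    imageq = (
        image.quality_factor
        if image.quality_factor is not None
        else compute_imageq(image)
    )
    if imageq <= config.quality_gate:
        return None, "quality_gate", image, gt
    try:
        boundaries = segment_boundaries(image)
    except SegmentationFailure:
        return None, "boundary_misidentification", image, gt
    qc = flag_misidentification(image, boundaries)
    if qc.misidentification:
        return None, "boundary_misidentification", image, gt
    measurement = measure_eye(image, boundaries, qc=qc)
    return measurement, None, image, gt


def run_pipeline(config: PipelineConfig, cohort=None) -> dict:
    """Execute all stages; return the run manifest.

    The manifest carries the exclusion accounting and, when ``out_dir``
    is set, the paths of every artifact written.  The merged cohort
    table (one row per recruited eye, measurements NaN for excluded
    eyes) is attached under the non-serialised key ``cohort``.  A
    pre-built list of SubjectTruth can be supplied to bypass sampling
    (scenario studies, controlled quality mixes).
    """
    if cohort is None:
        cohort = sample_cohort(config.params, config.n_eyes)
    elif len(cohort) != config.n_eyes:
        config = dataclasses.replace(config, n_eyes=len(cohort))
    truth_frame = cohort_to_frame(cohort)

    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True) if config.save_images else None

    records = []
    exclusions = {"quality_gate": 0, "boundary_misidentification": 0, "motion_artifact": 0}
    for truth in cohort:
        if truth.subject_id in config.motion_artifact_ids:
            reason, measurement = "motion_artifact", None
            image = gt = None
        else:
            measurement, reason, image, gt = process_eye(truth, config)
        if reason is not None:
            exclusions[reason] += 1
        row = {
            "subject_id": truth.subject_id, "age": truth.age, "sex": truth.sex,
            "se": truth.se, "bcva": truth.bcva, "al": truth.al, "iop": truth.iop,
            "vf_md": truth.vf_md, "laterality": truth.laterality,
            "excluded": reason or "",
        }
        if measurement is not None:
            row.update(measurement.to_row())
        else:
            row.update({c: np.nan for c in MEASUREMENT_COLUMNS})
            row.update({"imageq": np.nan, "qc_pass": False})
        records.append(row)
        if out_dir is not None and config.save_images and image is not None:
            write_image(image, out_dir / "images" / f"eye_{truth.subject_id:04d}.png")
            gt.to_json(out_dir / "images" / f"eye_{truth.subject_id:04d}_truth.json")

    merged = pd.DataFrame(records)
    n_analyzed = int((merged["excluded"] == "").sum())
    if n_analyzed + sum(exclusions.values()) != config.n_eyes:
        raise AssertionError("exclusion accounting does not conserve eye count")

    analyzed = merged[merged["excluded"] == ""]
    tables: dict[str, pd.DataFrame] = {}
    if n_analyzed >= 3:
        tables["age_groups"] = cohortstats.age_group_summary(
            analyzed, edges=config.age_edges
        )
        tables["sector_comparison"] = cohortstats.compare_sectors(analyzed)
        screen = cohortstats.univariable_screen(analyzed)
        tables["univariable"] = screen.to_frame()
        fit = cohortstats.multivariable_fit(
            analyzed,
            carry_forward=screen.carry_forward(config.alpha),
            forced=config.forced_covariates,
        )
        tables["multivariable"] = fit.to_frame()

    manifest = {
        "seed": config.seed,
        "n_recruited": config.n_eyes,
        "n_analyzed": n_analyzed,
        "excluded": exclusions,
        "quality_gate": config.quality_gate,
        "outputs": {},
    }

    if out_dir is not None:
        paths = {
            "cohort_truth": out_dir / "cohort_truth.csv",
            "cohort": out_dir / "cohort.csv",
        }
        truth_frame.to_csv(paths["cohort_truth"], index=False)
        merged.to_csv(paths["cohort"], index=False)
        for name, table in tables.items():
            paths[name] = out_dir / f"{name}.csv"
            table.to_csv(paths[name], index=False)
        # names are stored relative to the run directory so reruns into
        # different locations stay byte-identical
        manifest["outputs"] = {k: v.name for k, v in paths.items()}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    manifest["cohort"] = merged
    manifest["tables"] = tables
    return manifest


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the mandatory column schema; unknown
    columns are preserved untouched."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in MANDATORY_COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV missing mandatory column: {col!r}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def roundtrip_cohort(path: str | Path) -> pd.DataFrame:
    """Read -> write -> read identity check; returns the re-read table."""
    df = read_cohort(path)
    tmp = Path(str(path) + ".roundtrip.tmp")
    try:
        write_cohort(df, tmp)
        df2 = read_cohort(tmp)
    finally:
        tmp.unlink(missing_ok=True)
    if not df2.equals(df):
        raise AssertionError("cohort CSV did not round-trip identically")
    return df2
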