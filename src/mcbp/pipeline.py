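"""Pipeline orchestration and columnar-text I/O glue.

Stages (each usable on its own, chained by :func:`run_pipeline`):

1. ``build-table`` — Monte Carlo pressure sweep to an intensity table (CSV);
2. ``synth``       — synthetic cohort + PPG fixture on disk;
3. ``process-ppg`` — manifest of PPG segments to a per-subject feature CSV;
4. ``calibrate``   — boosted-tree calibration models per branch;
5. ``estimate``    — SBP/DBP/MAP estimates CSV;
6. ``evaluate``    — JSON evaluation report.

Every run directory receives a ``run_manifest.json`` recording the resolved
configuration and seeds, so any artifact is reproducible from its manifest.
CSV is the interchange format (headered, UTF-8); JSON for configs/reports.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import build_calibration_dataset, fit_calibration
from .evaluation import estimate_bp, evaluate_estimates
from .ppg import PpgSegment, SubjectRecord, extract_features
from .synth import CohortSpec, generate_end_to_end_fixture
from .table import IntensityTable, monotonize

__all__ = [
    "load_ppg_manifest",
    "process_cohort",
    "run_pipeline",
    "write_run_manifest",
]


def write_run_manifest(out_dir, config: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"mcbp_version": __version__,
                "python": platform.python_version(),
                "config": config}
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def load_ppg_manifest(manifest_path) -> dict:
    """Read a segment manifest CSV into {subject_id: [PpgSegment, ...]}.

    The manifest needs columns subject_id, segment_id, fs, path (paths
    relative to the manifest's directory); each segment file is a one-column
    CSV of raw samples.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    cohort: dict = {}
    for _, row in df.iterrows():
        seg_path = base / row["path"]
        if not seg_path.exists():
            raise FileNotFoundError(f"segment file not found: {seg_path}")
        samples = pd.read_csv(seg_path)["sample"].to_numpy()
        cohort.setdefault(str(row["subject_id"]), []).append(
            PpgSegment(samples=samples, fs=float(row["fs"]),
                       subject_id=str(row["subject_id"]),
                       segment_id=str(row["segment_id"])))
    return cohort


def process_cohort(cohort: dict, references: pd.DataFrame,
                   filter_band=(0.5, 8.0), order: int = 6,
                   value_source: str = "filtered_plus_dc") -> pd.DataFrame:
    """Extract the calibration feature table for every subject.

    Subjects without detectable beats are dropped (logged in the returned
    frame's ``attrs["failed"]``).
    """
    rows, failed = {}, []
    for sid, segments in sorted(cohort.items()):
        ref = references.loc[sid] if sid in references.index else None
        record = SubjectRecord(
            subject_id=sid, segments=segments,
            SBP=None if ref is None else float(ref["sbp"]),
            DBP=None if ref is None else float(ref["dbp"]),
            BMI=None if ref is None else float(ref.get("bmi", np.nan)),
            pulse_rate=None if ref is None else float(ref.get("pulse_rate", np.nan)),
        )
        try:
            feats = extract_features(record, filter_band, order=order,
                                     value_source=value_source)
        except RuntimeError:
            failed.append(sid)
            continue
        rows[sid] = {
            "systolic_intensity": feats.systolic_intensity,
            "diastolic_intensity": feats.diastolic_intensity,
            "skewness": feats.skewness,
            "kurtosis": feats.kurtosis,
            "bmi": record.BMI,
            "pulse_rate": record.pulse_rate,
            "n_beats": feats.n_beats,
            "pulse_rate_est": feats.pulse_rate_est,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    out.attrs["failed"] = failed
    return out


def run_pipeline(table: IntensityTable, cohort_spec: CohortSpec,
                 noise_level: float, seed: int, out_dir,
                 value_source: str = "filtered_plus_dc",
                 hyperparams: dict | None = None) -> dict:
    """Synthesize a cohort, run all downstream stages, return the report.

    The intensity table is monotonized once and shared by the coupling
    (generator), the calibration targets and the inversion.  Artifacts
    (fixture, features, estimates, report, run manifest) land in ``out_dir``.
    """
    from .synth import PROFILES

    out = Path(out_dir)
    mono = monotonize(table) if not table.monotone else table

    fixture_dir = out / "fixture"
    manifest_path, cohort_path, truth_path = generate_end_to_end_fixture(
        cohort_spec, mono, noise_level, seed, fixture_dir)
    cohort = load_ppg_manifest(manifest_path)
    references = pd.read_csv(cohort_path, index_col="subject_id")

    band = PROFILES[cohort_spec.profile]["filter_band"]
    features = process_cohort(cohort, references, filter_band=band,
                              value_source=value_source)
    features.to_csv(out / "features.csv")

    models = {}
    for branch in ("systolic", "diastolic"):
        ds = build_calibration_dataset(features, references, mono, branch)
        models[branch] = fit_calibration(ds, hyperparams=hyperparams, seed=seed)
        models[branch].save(str(out / f"model_{branch}.json"))

    estimates = estimate_bp(models["systolic"], models["diastolic"],
                            features, mono, mono)
    estimates.to_csv(out / "estimates.csv")

    truth = pd.read_csv(truth_path, index_col="subject_id")
    report = evaluate_estimates(estimates, truth)
    report["cv_r2"] = {b: models[b].cv_r2 for b in models}
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    write_run_manifest(out, {
        "stage": "run_pipeline", "seed": seed, "noise_level": noise_level,
        "cohort": asdict(cohort_spec), "value_source": value_source,
        "table_provenance": table.provenance,
    })
    return report
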