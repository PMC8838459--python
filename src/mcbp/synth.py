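"""Synthetic cohorts and PPG recordings for end-to-end testing.

Real PPG datasets cannot be redistributed, so this module generates cohorts
and recordings with the statistical structure the pipeline assumes:

* covariates (SBP, DBP, BMI, pulse rate, age) are drawn from truncated
  normal distributions matching the published summary statistics of the two
  device profiles (a 1 kHz "public"-style cohort and an 83 Hz
  "selfmade"-style cohort), with pairs rejected unless SBP > DBP + 10;
* each subject's PPG is a beat train built from a two-component
  (systolic + diastolic wave) pulse template; the systolic-peak and
  pulse-onset sample values are tied to the Monte Carlo intensity table at
  the subject's SBP and DBP through an affine device transform (gain,
  offset, polarity) with optional subject-level jitter;
* additive white noise and low-frequency baseline wander emulate sensor
  noise and respiration.

Everything is seed-deterministic.  The generator makes no attempt to model
arrhythmia, motion artifacts, or pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ppg import PpgSegment

__all__ = [
    "CohortSpec",
    "PpgGeneratorParams",
    "PROFILES",
    "generate_cohort",
    "generate_ppg",
    "generate_end_to_end_fixture",
]

# (mean, sd, min, max) per covariate, per device profile.
PROFILES = {
    "public": {
        "fs": 1000.0, "n_segments": 3, "duration_s": 2.1,
        "filter_band": (0.5, 25.0),
        "sbp": (124.42, 19.65, 80.0, 182.0),
        "dbp": (69.46, 10.46, 42.0, 96.0),
        "bmi": (23.23, 3.88, 15.94, 35.84),
        "pulse_rate": (73.2, 10.87, 52.0, 103.0),
        "age": (54.7, 16.35, 23.0, 85.0),
    },
    "selfmade": {
        "fs": 83.0, "n_segments": 1, "duration_s": 240.0,
        "filter_band": (0.5, 8.0),
        "sbp": (104.57, 11.65, 81.0, 133.0),
        "dbp": (75.8, 6.86, 62.0, 96.0),
        "bmi": (27.87, 2.96, 20.76, 34.6),
        "pulse_rate": (82.47, 10.49, 55.0, 108.0),
        "age": (30.4, 7.62, 25.0, 61.0),
    },
}

MIN_PULSE_PRESSURE = 10.0       # rejection bound: SBP must exceed DBP + 10


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, seed and device profile for covariate generation."""

    n_subjects: int = 30
    seed: int = 0
    profile: str = "selfmade"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class PpgGeneratorParams:
    """Waveform and device-transform parameters of the PPG generator.

    The pulse template is a sum of two Gaussian waves in beat phase (a
    dominant systolic wave and a smaller, later diastolic wave), rescaled
    per beat so the onset sample equals the DBP-coupled value and the
    systolic peak the SBP-coupled value.  ``polarity`` flips the optical
    signal the way a transmission front end does when more blood means less
    light; ``"auto"`` chooses the sign that makes systolic landmarks maxima.
    """

    gain: float = 1.0e6
    offset: float = 2.0e5
    polarity: str = "auto"              # "auto" | "positive" | "negative"
    subject_jitter_frac: float = 0.0    # sd of per-subject gain jitter
    beat_jitter_frac: float = 0.02      # uniform beat-period jitter (<= 3%)
    amp_jitter_frac: float = 0.0        # sd of per-beat amplitude jitter
    noise_frac: float = 0.0             # white-noise sd / pulse amplitude
    wander_frac: float = 0.0            # baseline-wander amplitude / pulse amp
    wander_freq_hz: float = 0.25        # respiration-band wander
    systolic_phase: float = 0.30
    systolic_width: float = 0.09
    diastolic_phase: float = 0.62
    diastolic_width: float = 0.14
    diastolic_height: float = 0.35

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        for name in ("subject_jitter_frac", "amp_jitter_frac",
                     "noise_frac", "wander_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.beat_jitter_frac <= 0.03:
            raise ValueError("beat_jitter_frac must lie in [0, 0.03]")

    def scaled(self, noise_level: float) -> "PpgGeneratorParams":
        """All stochastic amplitudes set proportional to one noise level."""
        return replace(
            self,
            noise_frac=noise_level,
            wander_frac=noise_level,
            amp_jitter_frac=noise_level / 2.0,
            subject_jitter_frac=noise_level / 2.0,
        )


def _trunc_draw(rng, stats, size):
    mean, sd, lo, hi = stats
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a covariate table for one cohort.

    Returns a DataFrame indexed by subject id with columns sbp, dbp, bmi,
    pulse_rate, age, sex.  SBP/DBP pairs violating SBP > DBP + 10 are
    redrawn jointly.
    """
    prof = PROFILES[spec.profile]
    if prof["sbp"][3] <= prof["dbp"][2] + MIN_PULSE_PRESSURE:
        raise ValueError("infeasible spec: SBP range cannot exceed DBP + 10")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sbp = _trunc_draw(rng, prof["sbp"], n)
    dbp = _trunc_draw(rng, prof["dbp"], n)
    for _ in range(1000):
        bad = sbp <= dbp + MIN_PULSE_PRESSURE
        if not bad.any():
            break
        sbp[bad] = _trunc_draw(rng, prof["sbp"], int(bad.sum()))
        dbp[bad] = _trunc_draw(rng, prof["dbp"], int(bad.sum()))
    else:
        raise RuntimeError("rejection sampling failed to satisfy SBP > DBP + 10")
    df = pd.DataFrame({
        "sbp": sbp,
        "dbp": dbp,
        "bmi": _trunc_draw(rng, prof["bmi"], n),
        "pulse_rate": _trunc_draw(rng, prof["pulse_rate"], n),
        "age": _trunc_draw(rng, prof["age"], n),
        "sex": rng.choice(["F", "M"], size=n),
    }, index=pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id"))
    return df


def _pulse_template(params: PpgGeneratorParams, u: np.ndarray) -> np.ndarray:
    return (
        np.exp(-0.5 * ((u - params.systolic_phase) / params.systolic_width) ** 2)
        + params.diastolic_height
        * np.exp(-0.5 * ((u - params.diastolic_phase) / params.diastolic_width) ** 2)
    )


def _resolve_polarity(params: PpgGeneratorParams, table) -> float:
    if params.polarity == "positive":
        return 1.0
    if params.polarity == "negative":
        return -1.0
    # auto: systolic landmarks must be signal maxima after the device
    return 1.0 if table.intensities[-1] >= table.intensities[0] else -1.0


def generate_ppg(subject: pd.Series, params: PpgGeneratorParams, table,
                 profile: str, rng: np.random.Generator) -> list:
    """Generate the PPG segments of one subject.

    ``subject`` is a cohort row (needs sbp, dbp, pulse_rate and a name);
    intensities at the systolic peak and pulse onset are
    ``polarity*gain*table(SBP or DBP) + offset`` plus configured jitter.
    """
    prof = PROFILES[profile]
    lo, hi = table.pressures[0], table.pressures[-1]
    if not (lo <= subject["dbp"] <= hi and lo <= subject["sbp"] <= hi):
        raise ValueError("subject pressures outside the intensity table range")
    sign = _resolve_polarity(params, table)
    gain_i = params.gain * (1.0 + params.subject_jitter_frac * rng.standard_normal())
    gain_i = max(gain_i, 0.1 * params.gain)
    s_level = sign * gain_i * float(table.interp(subject["sbp"])) + params.offset
    d_level = sign * gain_i * float(table.interp(subject["dbp"])) + params.offset
    pulse_amp = abs(s_level - d_level)

    # template extrema in beat phase, used to pin onset/peak sample values
    u_fine = np.linspace(0.0, 1.0, 2001)
    tpl_fine = _pulse_template(params, u_fine)
    tmin, tmax = tpl_fine.min(), tpl_fine.max()

    period = 60.0 / float(subject["pulse_rate"])
    segments = []
    for k in range(prof["n_segments"]):
        n_samples = int(round(prof["fs"] * prof["duration_s"]))
        t = np.arange(n_samples) / prof["fs"]
        n_beats = int(np.ceil(prof["duration_s"] / period)) + 2
        jitter = params.beat_jitter_frac * (2.0 * rng.random(n_beats) - 1.0)
        periods = period * (1.0 + jitter)
        onsets = np.concatenate([[0.0], np.cumsum(periods)])
        idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, n_beats - 1)
        u = (t - onsets[idx]) / periods[idx]
        shape = (_pulse_template(params, u) - tmin) / (tmax - tmin)
        amp_jit = params.amp_jitter_frac * pulse_amp * rng.standard_normal(n_beats)
        x = d_level + (s_level - d_level) * shape + amp_jit[idx] * shape
        x += (params.wander_frac * pulse_amp
              * np.sin(2.0 * np.pi * params.wander_freq_hz * t
                       + 2.0 * np.pi * rng.random()))
        x += params.noise_frac * pulse_amp * rng.standard_normal(n_samples)
        segments.append(PpgSegment(
            samples=x, fs=prof["fs"],
            subject_id=str(subject.name), segment_id=f"seg{k}",
        ))
    return segments


def generate_end_to_end_fixture(cohort_spec: CohortSpec, table,
                                noise_level: float, seed: int,
                                out_dir, params: PpgGeneratorParams | None = None):
    """Write a complete on-disk fixture: PPG files, manifest, cohort, truth.

    Layout under ``out_dir``: one CSV per segment (column ``sample``),
    ``manifest.csv`` (subject_id, segment_id, fs, path), ``cohort.csv``
    (covariates the pipeline may use) and ``truth.csv`` (the generating
    SBP/DBP, for parameter-recovery checks).  Regeneration with the same
    arguments is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (params or PpgGeneratorParams()).scaled(noise_level)
    cohort = generate_cohort(replace(cohort_spec, seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    manifest_rows = []
    for sid, row in cohort.iterrows():
        for seg in generate_ppg(row, params, table, cohort_spec.profile, rng):
            fname = f"{sid}_{seg.segment_id}.csv"
            np.savetxt(out / fname, seg.samples, fmt="%.6f",
                       header="sample", comments="")
            manifest_rows.append(
                {"subject_id": sid, "segment_id": seg.segment_id,
                 "fs": seg.fs, "path": fname})
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    cohort.round(6).to_csv(out / "cohort.csv")
    cohort[["sbp", "dbp"]].round(6).to_csv(out / "truth.csv")
    return out / "manifest.csv", out / "cohort.csv", out / "truth.csv"
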