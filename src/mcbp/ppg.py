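"""PPG signal conditioning, beat detection, quality statistics and features.

A fingertip PPG segment is band-pass filtered (zero-phase Butterworth, so
beat landmarks are not phase-shifted), systolic peaks are found as local
maxima above an adaptive moving-quantile threshold with a refractory period,
and pulse onsets are found by running the same detector on the negated
signal.  The systolic-peak and pulse-onset intensities, together with the
skewness and kurtosis of the raw signal, the subject's BMI and pulse rate,
form the feature vector handed to the calibration model.

Two device profiles are supported: a "public" profile (1 kHz sampling,
2.1 s segments, 0.5-25 Hz band) and a "selfmade" profile (83 Hz sampling,
240 s segments, 0.5-8 Hz band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "PpgSegment",
    "BeatFeatures",
    "SubjectRecord",
    "bandpass_filter",
    "detect_systolic_peaks",
    "detect_pulse_onsets",
    "signal_quality",
    "rank_subjects_by_quality",
    "extract_features",
]

# adaptive-threshold parameters of the peak detector
MIN_SEPARATION_FACTOR = 0.4     # fraction of the expected beat period
THRESHOLD_QUANTILE = 0.60       # moving quantile used as the height threshold
THRESHOLD_WINDOW_BEATS = 2.0    # quantile window length in beat periods


@dataclass(frozen=True)
class PpgSegment:
    """One PPG recording segment in raw device units."""

    samples: np.ndarray
    fs: float                   # sampling rate, Hz
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))


@dataclass(frozen=True)
class BeatFeatures:
    """Aggregated per-subject beat features."""

    systolic_intensity: float
    diastolic_intensity: float
    skewness: float
    kurtosis: float             # excess (Fisher) kurtosis
    n_beats: int
    pulse_rate_est: float       # beats/min

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.pulse_rate_est <= 0:
            raise ValueError("pulse_rate_est must be positive")


@dataclass
class SubjectRecord:
    """PPG segments plus reference covariates for one subject."""

    subject_id: str
    segments: list
    SBP: float | None = None
    DBP: float | None = None
    BMI: float | None = None
    pulse_rate: float | None = None
    features: BeatFeatures | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.SBP is not None and self.DBP is not None and self.SBP <= self.DBP:
            raise ValueError("SBP must exceed DBP")


def bandpass_filter(segment: PpgSegment, low_hz: float, high_hz: float,
                    order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth band-pass of the stated overall order.

    ``order`` is the order of the band-pass filter itself (must be even; the
    underlying prototype has ``order // 2`` pole pairs).  Applied forward and
    backward (``sosfiltfilt``), so the output has no phase shift, equal
    length, and no DC component.
    """
    fs = segment.fs
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {fs / 2} Hz")
    if order < 2 or order % 2:
        raise ValueError("order must be a positive even integer")
    sos = sps.butter(order // 2, [low_hz, high_hz], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, segment.samples)


def _moving_quantile_threshold(x: np.ndarray, window: int, q: float) -> np.ndarray:
    w = max(3, min(window, len(x)))
    return (pd.Series(x).rolling(w, center=True, min_periods=1)
            .quantile(q).to_numpy())


def detect_systolic_peaks(filtered: np.ndarray, fs: float,
                          pulse_rate_hint: float = 75.0) -> np.ndarray:
    """Indices of systolic peaks in a filtered PPG trace.

    Local maxima above a moving 60th-percentile threshold (window of two
    expected beat periods), separated by at least 0.4 expected beat periods.
    Returns an empty array when nothing qualifies.
    """
    filtered = np.asarray(filtered, dtype=float)
    if pulse_rate_hint <= 0:
        raise ValueError("pulse_rate_hint must be positive")
    period = 60.0 / pulse_rate_hint
    distance = max(1, int(round(MIN_SEPARATION_FACTOR * period * fs)))
    if len(filtered) < 2 or np.ptp(filtered) == 0:
        return np.array([], dtype=int)
    thr = _moving_quantile_threshold(
        filtered, int(round(THRESHOLD_WINDOW_BEATS * period * fs)),
        THRESHOLD_QUANTILE,
    )
    peaks, _ = sps.find_peaks(filtered, distance=distance)
    peaks = peaks[filtered[peaks] > thr[peaks]]
    return peaks.astype(int)


def detect_pulse_onsets(filtered: np.ndarray, fs: float,
                        pulse_rate_hint: float = 75.0) -> np.ndarray:
    """Indices of pulse onsets: the peak detector applied to the negated trace."""
    return detect_systolic_peaks(-np.asarray(filtered, dtype=float), fs,
                                 pulse_rate_hint)


def pair_onsets_peaks(onsets: np.ndarray, peaks: np.ndarray):
    """Pair each systolic peak with the nearest preceding onset.

    Returns (onsets, peaks) arrays of equal length with strictly alternating
    indices (onset < peak).
    """
    po, pp = [], []
    j = -1
    for pk in peaks:
        earlier = onsets[onsets < pk]
        if len(earlier) == 0:
            continue
        onset = earlier[-1]
        if po and onset == po[-1]:
            # two peaks share an onset: keep the taller association (first)
            continue
        po.append(onset)
        pp.append(pk)
    return np.array(po, dtype=int), np.array(pp, dtype=int)


def signal_quality(samples: np.ndarray):
    """(skewness, excess kurtosis) of a signal.

    Sample third and fourth standardized moments; kurtosis uses the Fisher
    convention (normal = 0).  Undefined for constant signals.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.var(x) == 0:
        raise ValueError("zero-variance signal: skewness/kurtosis undefined")
    return float(spstats.skew(x)), float(spstats.kurtosis(x, fisher=True))


def rank_subjects_by_quality(cohort: dict, top_n: int) -> list:
    """Select the ``top_n`` subject ids by summed per-segment skewness.

    ``cohort`` maps subject id to a list of :class:`PpgSegment`.  The score
    is the sum of segment skewness values; ties are broken by subject id,
    so the selection is deterministic.
    """
    if any(len(segs) == 0 for segs in cohort.values()):
        raise ValueError("every subject needs at least one segment")
    scores = {
        sid: sum(signal_quality(seg.samples)[0] for seg in segs)
        for sid, segs in cohort.items()
    }
    ordered = sorted(scores, key=lambda sid: (-scores[sid], sid))
    if top_n > len(ordered):
        import warnings

        warnings.warn("top_n exceeds cohort size; returning all subjects",
                      stacklevel=2)
    return ordered[:top_n]


def extract_features(record: SubjectRecord, filter_band=(0.5, 8.0),
                     order: int = 6, value_source: str = "filtered") -> BeatFeatures:
    """Filter, detect beats and aggregate the subject's feature vector.

    Systolic and diastolic intensities are the medians, across all beats of
    all segments, of the trace value at the detected peak and onset indices.
    ``value_source`` selects the trace the values are read from:

    - ``"filtered"`` (default): the band-passed, zero-mean trace;
    - ``"raw"``: the raw device-unit trace at the same indices;
    - ``"filtered_plus_dc"``: the band-passed trace plus the raw segment
      mean, i.e. denoised values restored to the device intensity scale.

    The pulse rate estimate comes from the median inter-peak interval;
    skewness/kurtosis from the concatenated raw segments.

    Raises RuntimeError when no beats are detected in any segment.
    """
    if value_source not in ("filtered", "raw", "filtered_plus_dc"):
        raise ValueError(f"unknown value_source {value_source!r}")
    hint = record.pulse_rate or 75.0
    sys_vals, dia_vals, intervals = [], [], []
    n_beats = 0
    ordered = sorted(record.segments, key=lambda s: s.segment_id)
    for seg in ordered:
        filt = bandpass_filter(seg, *filter_band, order=order)
        peaks = detect_systolic_peaks(filt, seg.fs, hint)
        onsets = detect_pulse_onsets(filt, seg.fs, hint)
        onsets, peaks = pair_onsets_peaks(onsets, peaks)
        if len(peaks) == 0:
            continue
        if value_source == "filtered":
            trace_p, trace_o = filt, filt
        elif value_source == "raw":
            trace_p = trace_o = seg.samples
        else:
            dc = float(seg.samples.mean())
            trace_p = trace_o = filt + dc
        sys_vals.extend(trace_p[peaks])
        dia_vals.extend(trace_o[onsets])
        n_beats += len(peaks)
        if len(peaks) > 1:
            intervals.extend(np.diff(peaks) / seg.fs)
    if n_beats == 0:
        raise RuntimeError(f"no beats detected for subject {record.subject_id!r}")
    if intervals:
        pulse_rate_est = 60.0 / float(np.median(intervals))
    else:
        pulse_rate_est = hint
    raw_concat = np.concatenate([seg.samples for seg in ordered])
    skew, kurt = signal_quality(raw_concat)
    return BeatFeatures(
        systolic_intensity=float(np.median(sys_vals)),
        diastolic_intensity=float(np.median(dia_vals)),
        skewness=skew, kurtosis=kurt,
        n_beats=int(n_beats), pulse_rate_est=pulse_rate_est,
    )
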