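"""Raw PPG recording -> 144-sample normalized representative pulse.

The pipeline is: FIR bandpass (0.5-10 Hz, taps = sampling rate) -> 50 ms
moving-average smoothing -> adaptive-threshold onset detection -> onset-to-
onset segmentation -> pulse-to-pulse-interval (PPI) outlier gate
(Q1 - 1.5*QD, Q3 + 1.5*QD) -> per-sample median template at the median PPI
length -> 50 ms smoothing -> resample to 144 samples -> min-max normalize
to [0, 1].  Each stage is exposed as its own function so the intermediate
contracts can be tested independently; ``preprocess_recording`` composes
them and logs per-stage counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import firwin

from .errors import (ConfigurationError, InputError, NormalizationError,
                     SegmentationError, UnusableRecordingError)

__all__ = [
    "PULSE_LENGTH",
    "FilterSpec",
    "PulseSegment",
    "PPISeries",
    "RepresentativePulse",
    "StageLog",
    "design_bandpass",
    "apply_fir",
    "smooth",
    "detect_onsets",
    "segment",
    "ppi_outlier_bounds",
    "filter_segments",
    "representative_pulse",
    "preprocess_recording",
]

#: Fixed model input length (samples).
PULSE_LENGTH = 144

SUPPORTED_RATES = (125, 250)


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR bandpass description, taps included."""

    passband_low: float
    passband_high: float
    n_taps: int
    sampling_rate: float
    taps: np.ndarray

    @property
    def group_delay(self) -> int:
        # integer part of (n_taps - 1) / 2; for even tap counts the
        # residual half-sample shift is below landmark tolerance
        return (self.n_taps - 1) // 2


@dataclass
class PulseSegment:
    """One onset-to-onset pulse cut from a recording."""

    samples: np.ndarray
    onset_index: int
    ppi: float


@dataclass
class PPISeries:
    """Pulse-to-pulse intervals with quartile-based outlier bounds.

    QD is the quantile deviation (Q3 - Q1) / 2; the gate excludes intervals
    below Q1 - 1.5*QD or above Q3 + 1.5*QD. ``mode='iqr'`` substitutes the
    full interquartile range for QD, which can only widen the bounds.
    """

    ppis: np.ndarray
    q1: float
    q3: float
    qd: float
    lower_bound: float
    upper_bound: float
    mode: str = "qd"

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


@dataclass
class RepresentativePulse:
    """The per-subject median pulse template fed to the regressor.

    Exactly 144 samples, min 0 and max 1 after normalization.
    """

    samples: np.ndarray
    source_subject: str = ""
    n_segments_used: int = 0
    median_ppi: float = float("nan")

    def validate(self) -> None:
        if len(self.samples) != PULSE_LENGTH:
            raise InputError(f"representative pulse length {len(self.samples)} != {PULSE_LENGTH}")
        if not (np.isclose(self.samples.min(), 0.0)
                and np.isclose(self.samples.max(), 1.0)):
            raise InputError("representative pulse not normalized to [0, 1]")


@dataclass
class StageLog:
    """Per-stage record counts and warnings for one recording."""

    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add(self, stage: str, count: int) -> None:
        self.counts[stage] = int(count)

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append((stage, message))


def design_bandpass(sampling_rate: float, passband=(0.5, 10.0),
                    allow_any_rate: bool = False) -> FilterSpec:
    """Windowed-sinc (Hamming) linear-phase FIR bandpass.

    The tap count equals the sampling rate (a one-second impulse
    response), so the filter resolves the 0.5 Hz lower edge at either
    supported rate. Rates other than 125/250 Hz require an explicit
    override.
    """
    if sampling_rate not in SUPPORTED_RATES and not allow_any_rate:
        raise ConfigurationError(
            f"sampling rate {sampling_rate} unsupported (125 or 250 Hz); "
            "pass allow_any_rate=True to override")
    n_taps = int(round(sampling_rate))
    lo, hi = passband
    if not 0 < lo < hi < sampling_rate / 2:
        raise ConfigurationError(f"passband {passband} invalid for fs={sampling_rate}")
    taps = firwin(n_taps, [lo, hi], pass_zero=False, fs=sampling_rate,
                  window="hamming")
    return FilterSpec(lo, hi, n_taps, float(sampling_rate), taps)


def apply_fir(signal: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Filter and compensate the constant group delay.

    Output has the same length as the input and pulse landmarks keep their
    sample positions (up to the half-sample residual for even tap counts).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) <= spec.n_taps:
        raise InputError("signal must be 1-D and longer than the filter")
    full = np.convolve(signal, spec.taps, mode="full")
    d = spec.group_delay
    return full[d:d + len(signal)]


def smooth(signal: np.ndarray, sampling_rate: float,
           window_ms: float = 50.0) -> np.ndarray:
    """Centered moving average with a 50 ms window (forced odd), reflect-padded."""
    signal = np.asarray(signal, dtype=float)
    w = int(round(window_ms / 1000.0 * sampling_rate))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    if w == 1:
        return signal.copy()
    half = w // 2
    padded = np.pad(signal, half, mode="reflect")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def detect_onsets(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Adaptive-threshold pulse-onset detection.

    Works on the first difference (upstroke slope): a detection threshold
    decays exponentially from a fraction of the last accepted upstroke's
    peak slope toward a noise floor; each crossing (outside a 0.3 s
    refractory window) marks a systolic upstroke, and the onset is the
    signal minimum in a short backward window.  Expects a filtered,
    smoothed signal.  Returns a strictly increasing index array; empty
    (with a warning) when no upstrokes are found.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=np.int64)
    d = np.diff(x)
    pos = d[d > 0]
    if pos.size == 0:
        warnings.warn("no rising slopes found; returning no onsets")
        return np.array([], dtype=np.int64)
    # 90th percentile of the rising slopes: robust to short high-slope
    # artifact bursts, unlike the extreme upper tail
    global_ref = float(np.percentile(pos, 90))
    if global_ref <= 0:
        warnings.warn("flat signal; returning no onsets")
        return np.array([], dtype=np.int64)
    floor = 0.1 * global_ref
    refractory = int(round(0.3 * sampling_rate))
    tau = 1.5 * sampling_rate          # decay time constant, samples
    search_fwd = int(round(0.2 * sampling_rate))
    search_back = int(round(0.2 * sampling_rate))

    onsets = []
    last_amp = global_ref
    last_i = 0
    i = 1
    n = len(d)
    while i < n:
        thr = floor + (0.5 * last_amp - floor) * np.exp(-(i - last_i) / tau)
        thr = max(thr, floor)
        if d[i] > thr:
            peak_win = d[i:min(n, i + search_fwd)]
            last_amp = float(peak_win.max())
            back = x[max(0, i - search_back):i + 1]
            onset = max(0, i - search_back) + int(np.argmin(back))
            # refine from the valley to the upstroke foot: skip the flat
            # run where the slope is still < 25% of the upstroke peak
            limit = min(n, onset + int(round(0.1 * sampling_rate)))
            while onset < limit and d[onset] < 0.25 * last_amp:
                onset += 1
            if not onsets or onset - onsets[-1] >= refractory:
                onsets.append(onset)
                last_i = i
            i += refractory
        else:
            i += 1
    if not onsets:
        warnings.warn("no pulse onsets detected")
    return np.array(onsets, dtype=np.int64)


def segment(signal: np.ndarray, onsets: np.ndarray,
            sampling_rate: float) -> tuple[list[PulseSegment], np.ndarray]:
    """Cut half-open [onset_i, onset_{i+1}) segments; PPIs in seconds."""
    signal = np.asarray(signal, dtype=float)
    onsets = np.asarray(onsets, dtype=np.int64)
    if len(onsets) < 2:
        raise SegmentationError(f"need >= 2 onsets to segment, got {len(onsets)}")
    segments = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        segments.append(PulseSegment(samples=signal[a:b].copy(),
                                     onset_index=int(a),
                                     ppi=(b - a) / sampling_rate))
    ppis = np.diff(onsets) / sampling_rate
    return segments, ppis


def ppi_outlier_bounds(ppis: np.ndarray, mode: str = "qd") -> PPISeries:
    """Quartile-based interval-outlier bounds.

    Quartiles use linear interpolation between order statistics.  The
    default spread is the quantile deviation QD = (Q3 - Q1)/2; ``mode='iqr'``
    uses the full Q3 - Q1.  With fewer than four intervals no gating is
    possible: infinite bounds are returned with a warning.
    """
    ppis = np.asarray(ppis, dtype=float)
    if mode not in ("qd", "iqr"):
        raise ConfigurationError(f"unknown outlier mode {mode!r}")
    if len(ppis) < 4:
        warnings.warn("fewer than 4 intervals; retaining all segments")
        return PPISeries(ppis, float("nan"), float("nan"), float("nan"),
                         -np.inf, np.inf, mode)
    q1, q3 = np.quantile(ppis, [0.25, 0.75])  # linear interpolation
    qd = (q3 - q1) / 2.0
    spread = qd if mode == "qd" else (q3 - q1)
    return PPISeries(ppis, float(q1), float(q3), float(qd),
                     float(q1 - 1.5 * spread), float(q3 + 1.5 * spread), mode)


def filter_segments(segments: list[PulseSegment],
                    bounds) -> list[PulseSegment]:
    """Retain segments whose PPI lies inside the closed bounds interval."""
    if isinstance(bounds, PPISeries):
        lo, hi = bounds.bounds
    else:
        lo, hi = bounds
    retained = [s for s in segments if lo <= s.ppi <= hi]
    if segments and not retained:
        raise UnusableRecordingError("all segments rejected by the PPI gate")
    return retained


def _resample_cubic(y: np.ndarray, target_len: int) -> np.ndarray:
    """Cubic-spline resample to target_len over a common [0, 1] axis."""
    y = np.asarray(y, dtype=float)
    if len(y) == target_len:
        return y.copy()
    if len(y) < 4:  # spline needs 4 points; fall back to linear
        x_old = np.linspace(0.0, 1.0, len(y))
        return np.interp(np.linspace(0.0, 1.0, target_len), x_old, y)
    x_old = np.linspace(0.0, 1.0, len(y))
    return CubicSpline(x_old, y)(np.linspace(0.0, 1.0, target_len))


def representative_pulse(retained: list[PulseSegment], sampling_rate: float,
                         source_subject: str = "") -> RepresentativePulse:
    """Median-template the retained segments into the 144-sample input.

    Each segment is cubic-spline resampled to the median-PPI length, the
    per-sample median is taken across segments (robust to residual
    artifact beats), the template is smoothed with the 50 ms moving
    average, resampled to 144 samples, and finally min-max normalized so
    the output spans [0, 1] exactly.
    """
    if not retained:
        raise UnusableRecordingError("no segments to build a representative pulse")
    median_ppi = float(np.median([s.ppi for s in retained]))
    target_len = max(int(round(median_ppi * sampling_rate)), 4)
    stack = np.vstack([_resample_cubic(s.samples, target_len) for s in retained])
    template = np.median(stack, axis=0)
    template = smooth(template, sampling_rate)
    resized = _resample_cubic(template, PULSE_LENGTH)
    lo, hi = resized.min(), resized.max()
    if hi - lo <= 0:
        raise NormalizationError("flat template: max equals min")
    samples = (resized - lo) / (hi - lo)
    pulse = RepresentativePulse(samples=samples, source_subject=source_subject,
                                n_segments_used=len(retained),
                                median_ppi=median_ppi)
    pulse.validate()
    return pulse


def preprocess_recording(signal: np.ndarray, sampling_rate: float,
                         subject_id: str = "", iqr_mode: str = "qd",
                         filter_spec: FilterSpec | None = None
                         ) -> tuple[RepresentativePulse, StageLog]:
    """Full preprocessing chain for one recording.

    Returns the representative pulse plus a stage log whose segment counts
    are non-increasing (each stage only removes beats).  Raises
    ``UnusableRecordingError`` when no usable segment survives.
    """
    log = StageLog()
    spec = filter_spec or design_bandpass(sampling_rate)
    filtered = apply_fir(signal, spec)
    smoothed = smooth(filtered, sampling_rate)
    log.add("n_samples", len(smoothed))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        onsets = detect_onsets(smoothed, sampling_rate)
        for w in caught:
            log.warn("detect_onsets", str(w.message))
    log.add("onsets", len(onsets))
    if len(onsets) < 2:
        raise UnusableRecordingError(
            f"only {len(onsets)} onsets detected in {subject_id or 'recording'}")

    segments, ppis = segment(smoothed, onsets, sampling_rate)
    log.add("segments", len(segments))
    beats_per_min = len(segments) / (len(smoothed) / sampling_rate) * 60.0
    if beats_per_min < 20.0:
        # far below any physiological heart rate: the "beats" are filter
        # transients or artifacts, not pulses
        raise UnusableRecordingError(
            f"implausible beat rate {beats_per_min:.1f}/min in "
            f"{subject_id or 'recording'}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        series = ppi_outlier_bounds(ppis, mode=iqr_mode)
        for w in caught:
            log.warn("ppi_outlier_bounds", str(w.message))
    retained = filter_segments(segments, series)
    log.add("retained", len(retained))

    pulse = representative_pulse(retained, sampling_rate, subject_id)
    log.add("used", pulse.n_segments_used)
    return pulse, log
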