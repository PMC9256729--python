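"""Synthetic aging-PPG cohort generator.

Real finger/nasal PPG datasets with age labels are rarely public, so this
module synthesises recordings whose waveform morphology encodes age through
the incident/reflected-wave structure of the pulse: each beat is the sum of
an incident (systolic) Gaussian wave and a reflected (diastolic) Gaussian
wave, with the reflected wave arriving earlier and larger as the simulated
arteries stiffen with age.  Recordings add beat-to-beat interval jitter,
respiratory baseline wander, broadband noise, motion-artifact bursts and
occasional ectopic beats, so every downstream stage (filtering, onset
detection, interval-outlier gating, templating, regression) is exercised
under known ground truth.

The two-Gaussian-plus-notch pulse model is a deliberate abstraction: it is
not a hemodynamic simulation, and the affine age maps below are package
choices, not measured physiology.  See docs/methods.md for what this
generator does and does not emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, ConfigurationError

__all__ = [
    "PulseModelParams",
    "AgingMap",
    "CohortSpec",
    "RecordingLog",
    "SubjectRecord",
    "age_to_params",
    "synth_pulse",
    "synth_recording",
    "synth_cohort",
    "write_cohort",
    "COVARIATE_NAMES",
    "COVARIATE_PREVALENCE",
]

COVARIATE_NAMES = ("hypertension", "diabetes", "alcohol", "smoking")

# Bernoulli prevalences for the covariate flags, chosen to resemble a
# middle-aged surgical cohort.  Flags are independent of the waveform.
COVARIATE_PREVALENCE = {
    "hypertension": 0.27,
    "diabetes": 0.09,
    "alcohol": 0.29,
    "smoking": 0.15,
}


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of a single synthetic pulse.

    Times and widths are in seconds, amplitudes in arbitrary units.
    ``reflected_delay`` is the transit-time gap between the incident and
    reflected wave centres; it shortens with arterial stiffening and is the
    primary age signal the regressor must recover.
    """

    systolic_time: float = 0.17
    systolic_amp: float = 1.0
    systolic_width: float = 0.09
    reflected_delay: float = 0.30
    reflected_amp_ratio: float = 0.5
    reflected_width: float = 0.14
    notch_depth: float = 0.25

    def validate(self) -> None:
        if not (self.systolic_width > 0 and self.reflected_width > 0
                and self.reflected_delay > 0 and self.systolic_time > 0):
            raise ParameterError("widths, delays and times must be strictly positive")
        if not 0.0 <= self.reflected_amp_ratio < 1.5:
            raise ParameterError(
                f"reflected_amp_ratio {self.reflected_amp_ratio} outside [0, 1.5)")
        if not 0.0 <= self.notch_depth <= 1.0:
            raise ParameterError(f"notch_depth {self.notch_depth} outside [0, 1]")


#: (intercept, slope) pairs: mean parameter value = intercept + slope * age.
_DEFAULT_AFFINE = {
    "systolic_time": (0.17, 0.0),
    "systolic_amp": (1.0, 0.0),
    "systolic_width": (0.09, 0.0),
    "reflected_delay": (0.36, -0.0022),   # strictly decreasing with age
    "reflected_amp_ratio": (0.35, 0.004),  # non-decreasing with age
    "reflected_width": (0.14, 0.0),
    "notch_depth": (0.25, 0.0),
}

#: Between-subject jitter SDs around the affine means.
_DEFAULT_JITTER = {
    "systolic_time": 0.010,
    "systolic_amp": 0.05,
    "systolic_width": 0.005,
    "reflected_delay": 0.010,
    "reflected_amp_ratio": 0.02,
    "reflected_width": 0.008,
    "notch_depth": 0.03,
}

#: Hard clamps keeping jittered parameters inside PulseModelParams invariants.
_CLAMPS = {
    "systolic_time": (0.05, 0.40),
    "systolic_amp": (0.2, 5.0),
    "systolic_width": (0.03, 0.25),
    "reflected_delay": (0.05, 0.60),
    "reflected_amp_ratio": (0.0, 1.49),
    "reflected_width": (0.04, 0.30),
    "notch_depth": (0.0, 1.0),
}


@dataclass(frozen=True)
class AgingMap:
    """Affine maps age (years) -> pulse-parameter means, plus jitter SDs.

    The defaults encode faster, stronger wave reflection with age:
    ``reflected_delay`` mean strictly decreasing, ``reflected_amp_ratio``
    mean non-decreasing.  These coefficients are package choices.
    """

    affine: dict = field(default_factory=lambda: dict(_DEFAULT_AFFINE))
    jitter_sd: dict = field(default_factory=lambda: dict(_DEFAULT_JITTER))

    def mean_params(self, age: float) -> PulseModelParams:
        vals = {k: a + b * age for k, (a, b) in self.affine.items()}
        vals = {k: float(np.clip(v, *_CLAMPS[k])) for k, v in vals.items()}
        return PulseModelParams(**vals)

    def zero_jitter(self) -> "AgingMap":
        return AgingMap(affine=dict(self.affine),
                        jitter_sd={k: 0.0 for k in self.jitter_sd})


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``duration`` defaults to 180 s (3-minute recordings) and
    ``sampling_rate`` to 125 Hz; ``respiration_freq`` sits at 0.25 Hz, near
    the low edge of the analysis passband, so baseline removal is actually
    tested.  ``artifact_rate`` is in bursts per minute and ``ectopic_rate``
    is the per-beat probability of an interval outlier.
    """

    n_subjects: int = 70
    age_low: int = 20
    age_high: int = 89
    sampling_rate: int = 125
    duration: float = 180.0
    mean_ppi: float = 0.9
    ppi_jitter_sd: float = 0.03
    respiration_freq: float = 0.25
    respiration_amp: float = 0.05
    noise_sd: float = 0.01
    artifact_rate: float = 0.5
    ectopic_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.age_low < self.age_high:
            raise ConfigurationError("age_low must be < age_high")
        if self.sampling_rate not in (125, 250):
            raise ConfigurationError("sampling_rate must be 125 or 250 Hz")
        for name in ("ppi_jitter_sd", "respiration_amp", "noise_sd",
                     "artifact_rate", "ectopic_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.3 <= self.mean_ppi <= 2.5:
            raise ConfigurationError("mean_ppi outside plausible beat periods")


@dataclass
class RecordingLog:
    """Ground-truth event log for one synthetic recording."""

    onsets: np.ndarray            # sample index of each beat onset
    ppis: np.ndarray              # per-beat interval, s
    ectopic_beats: np.ndarray     # indices into ppis of interval outliers
    artifact_windows: list        # (start, end) sample windows of bursts

    @property
    def n_beats(self) -> int:
        return len(self.ppis)


@dataclass
class SubjectRecord:
    """One subject: signal, age label, covariate flags and ground truth."""

    subject_id: str
    age: float
    signal: np.ndarray
    sampling_rate: int
    ground_truth_params: PulseModelParams
    log: RecordingLog
    hypertension: bool = False
    diabetes: bool = False
    alcohol: bool = False
    smoking: bool = False
    seed: int = 0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def age_to_params(age: float, aging_map: AgingMap | None = None,
                  seed=0) -> PulseModelParams:
    """Draw pulse parameters for a subject of a given age.

    Means come from the aging map's affine coefficients; per-parameter
    Gaussian jitter (seeded) models between-subject variability.  With all
    jitter SDs zero the result is a deterministic function of age.
    """
    if not 0.0 <= age <= 120.0:
        raise DomainError(f"age {age} outside [0, 120] years")
    aging_map = aging_map or AgingMap()
    rng = _as_rng(seed)
    base = aging_map.mean_params(age)
    vals = {}
    for name in _DEFAULT_AFFINE:
        sd = aging_map.jitter_sd.get(name, 0.0)
        v = getattr(base, name)
        if sd > 0:
            v = v + rng.normal(0.0, sd)
        vals[name] = float(np.clip(v, *_CLAMPS[name]))
    params = PulseModelParams(**vals)
    params.validate()
    return params


def synth_pulse(params: PulseModelParams, ppi: float,
                sampling_rate: float) -> np.ndarray:
    """Render one pulse of ``round(ppi * sampling_rate)`` samples.

    The waveform is the sum of an incident Gaussian at ``systolic_time``,
    a reflected Gaussian delayed by ``reflected_delay``, minus a narrow
    notch term between them (disabled when the reflected wave is absent).
    A linear baseline through the endpoint values is subtracted so the
    pulse starts and ends at zero — the onset-to-onset convention with the
    minimum at the segment boundary — and the result is nonnegative.
    """
    params.validate()
    if ppi <= params.reflected_delay + params.reflected_width:
        raise ParameterError(
            f"ppi {ppi:.3f}s too short for reflected_delay+width "
            f"{params.reflected_delay + params.reflected_width:.3f}s")
    n = int(round(ppi * sampling_rate))
    t = np.arange(n) / sampling_rate
    w = _pulse_waveform(params, t)
    # remove the linear baseline through the analytic endpoint values so
    # consecutive beats concatenate continuously at zero
    w0 = _pulse_waveform(params, np.array([0.0]))[0]
    w1 = _pulse_waveform(params, np.array([ppi]))[0]
    w = w - (w0 + (w1 - w0) * t / ppi)
    # the late-diastolic tail can undershoot the endpoint line slightly;
    # clipping gives a flat diastolic baseline at zero, keeping the pulse
    # nonnegative with its minimum at the segment boundary
    return np.clip(w, 0.0, None)


def _pulse_waveform(params: PulseModelParams, t: np.ndarray) -> np.ndarray:
    p = params
    inc = p.systolic_amp * np.exp(-0.5 * ((t - p.systolic_time) / p.systolic_width) ** 2)
    if p.reflected_amp_ratio <= 0.0:
        return inc
    t_refl = p.systolic_time + p.reflected_delay
    refl = (p.reflected_amp_ratio * p.systolic_amp
            * np.exp(-0.5 * ((t - t_refl) / p.reflected_width) ** 2))
    # narrow depression between the two wave crests (dicrotic notch)
    t_notch = p.systolic_time + 0.5 * p.reflected_delay
    w_notch = max(p.reflected_delay / 4.0, 0.01)
    notch = (p.notch_depth * p.reflected_amp_ratio * 0.5 * p.systolic_amp
             * np.exp(-0.5 * ((t - t_notch) / w_notch) ** 2))
    return inc + refl - notch


def synth_recording(age: float, spec: CohortSpec, seed: int,
                    aging_map: AgingMap | None = None,
                    params: PulseModelParams | None = None) -> SubjectRecord:
    """Assemble a full recording for one subject.

    Beats with seeded interval jitter are concatenated; ectopic beats scale
    one interval by ~0.5x or ~1.8x the mean (interval outliers the
    preprocessing gate must reject).  A respiratory sinusoid, white noise
    and band-limited high-amplitude artifact bursts are then superimposed.
    The returned record carries the ground-truth event log.
    """
    spec.validate()
    rng = _as_rng(seed)
    aging_map = aging_map or AgingMap()
    if params is None:
        params = age_to_params(age, aging_map, rng)

    fs = spec.sampling_rate
    n_total = int(round(spec.duration * fs))
    min_ppi = params.reflected_delay + params.reflected_width + 0.05

    chunks, onsets, ppis, ectopics = [], [], [], []
    pos = 0
    beat = 0
    while pos < n_total:
        ppi = spec.mean_ppi + (rng.normal(0.0, spec.ppi_jitter_sd)
                               if spec.ppi_jitter_sd > 0 else 0.0)
        ppi = float(np.clip(ppi, 0.4, 2.2))
        is_ectopic = spec.ectopic_rate > 0 and rng.random() < spec.ectopic_rate
        if is_ectopic:
            ppi *= 0.5 if rng.random() < 0.5 else 1.8
            ectopics.append(beat)
        # an ectopic short interval may truncate the waveform mid-pulse
        render_ppi = max(ppi, min_ppi)
        pulse = synth_pulse(params, render_ppi, fs)
        n_keep = int(round(ppi * fs))
        pulse = pulse[:n_keep] if n_keep <= len(pulse) else np.pad(
            pulse, (0, n_keep - len(pulse)))
        onsets.append(pos)
        ppis.append(ppi)
        chunks.append(pulse)
        pos += n_keep
        beat += 1

    signal = np.concatenate(chunks)[:n_total]
    onsets = np.array([o for o in onsets if o < n_total], dtype=np.int64)
    ppis = np.array(ppis[: len(onsets)])
    ectopics = np.array([e for e in ectopics if e < len(onsets)], dtype=np.int64)

    t = np.arange(n_total) / fs
    if spec.respiration_amp > 0:
        signal = signal + spec.respiration_amp * np.sin(
            2 * np.pi * spec.respiration_freq * t)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, n_total)

    artifact_windows = []
    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration / 60.0)
        for _ in range(n_events):
            dur = rng.uniform(0.3, 1.0)
            n_burst = int(round(dur * fs))
            start = int(rng.integers(0, max(1, n_total - n_burst)))
            burst = _bandlimited_noise(n_burst, fs, rng) * 3.0 * params.systolic_amp
            signal[start:start + n_burst] += burst
            artifact_windows.append((start, start + n_burst))

    log = RecordingLog(onsets=onsets, ppis=ppis, ectopic_beats=ectopics,
                       artifact_windows=artifact_windows)
    return SubjectRecord(
        subject_id="", age=age, signal=signal, sampling_rate=fs,
        ground_truth_params=params, log=log, seed=int(seed) if np.isscalar(seed) else 0)


def _bandlimited_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """White noise band-limited to ~3-15 Hz (inside the analysis passband,
    so motion bursts survive filtering and must be handled downstream)."""
    from scipy.signal import butter, filtfilt
    white = rng.normal(0.0, 1.0, max(n, 64))
    b, a = butter(2, [3.0, min(15.0, 0.45 * fs)], btype="band", fs=fs)
    shaped = filtfilt(b, a, white)[:n]
    peak = np.max(np.abs(shaped)) or 1.0
    return shaped / peak


def _decade_allocation(n: int, bins: list[tuple[int, int]]) -> list[int]:
    """Spread n subjects over decade bins: equal base share, remainder to
    the earliest bins. Every bin is nonempty when n >= len(bins)."""
    k = len(bins)
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def decade_bins(age_low: int, age_high: int) -> list[tuple[int, int]]:
    """Inclusive decade bins covering [age_low, age_high]."""
    lo = (int(age_low) // 10) * 10
    bins = []
    while lo <= age_high:
        hi = lo + 9
        bins.append((max(lo, int(age_low)), min(hi, int(age_high))))
        lo += 10
    return bins


def synth_cohort(spec: CohortSpec, aging_map: AgingMap | None = None
                 ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a cohort plus its ground-truth manifest.

    Ages are decade-stratified uniform over [age_low, age_high]; covariate
    flags are independent Bernoulli draws; all randomness derives from
    ``spec.seed`` so the same spec reproduces a byte-identical manifest.
    """
    spec.validate()
    aging_map = aging_map or AgingMap()
    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss.spawn(1)[0])

    bins = decade_bins(spec.age_low, spec.age_high)
    counts = _decade_allocation(spec.n_subjects, bins)
    ages = []
    for (lo, hi), c in zip(bins, counts):
        ages.extend(master.integers(lo, hi + 1, size=c).tolist())
    ages = np.array(ages[: spec.n_subjects])
    master.shuffle(ages)

    records, rows = [], []
    child_seeds = ss.spawn(spec.n_subjects)
    for i, (age, child) in enumerate(zip(ages, child_seeds)):
        sid = f"S{i:04d}"
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(sub_seed)
        covs = {c: bool(rng.random() < COVARIATE_PREVALENCE[c])
                for c in COVARIATE_NAMES}
        rec = synth_recording(float(age), spec, rng, aging_map)
        rec.subject_id = sid
        rec.seed = sub_seed
        for c, v in covs.items():
            setattr(rec, c, v)
        records.append(rec)
        rows.append({
            "subject_id": sid, "age": int(age),
            "sampling_rate": spec.sampling_rate, **covs,
            "seed": sub_seed, "signal_path": "",
        })
    manifest = pd.DataFrame(rows)
    return records, manifest


def write_cohort(records: list[SubjectRecord], manifest: pd.DataFrame,
                 outdir) -> str:
    """Write signal files (single-column CSV) and the manifest CSV.

    Returns the manifest path. Signal paths in the manifest are relative to
    the manifest's directory.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    sigdir = os.path.join(outdir, "signals")
    os.makedirs(sigdir, exist_ok=True)
    manifest = manifest.copy()
    for rec in records:
        rel = os.path.join("signals", f"{rec.subject_id}.csv")
        np.savetxt(os.path.join(outdir, rel), rec.signal, fmt="%.6f")
        manifest.loc[manifest.subject_id == rec.subject_id, "signal_path"] = rel
    path = os.path.join(outdir, "manifest.csv")
    manifest.to_csv(path, index=False)
    return path
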