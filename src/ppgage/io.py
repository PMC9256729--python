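"""Tabular interchange formats, manifest validation and cohort screening.

All interchange is CSV.  Files written by this module start with a
``# ppgage-schema: <name>-v1`` comment line; readers skip comment lines,
so the files round-trip losslessly.

Column schemas
--------------
manifest:  subject_id, age, sampling_rate, hypertension, diabetes,
           alcohol, smoking, seed, signal_path
pulses:    subject_id, age, n_segments_used, median_ppi, s000..s143
preds:     subject_id, age, predicted_age, fold
saliency:  subject_id (or decade), g000..g143 [, p000..p143]
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import PULSE_LENGTH

__all__ = [
    "write_csv",
    "read_csv",
    "read_manifest",
    "load_signal",
    "pulses_to_frame",
    "frame_to_pulses",
    "screen_recordings",
]

MANIFEST_REQUIRED = ("subject_id", "age", "sampling_rate", "signal_path")
SUPPORTED_RATES = (125, 250)


def write_csv(df: pd.DataFrame, path: str, schema: str) -> None:
    """Write a CSV with a schema-version comment header."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# ppgage-schema: {schema}-v1\n")
        df.to_csv(fh, index=False)


def read_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_manifest(path: str, allow_any_rate: bool = False,
                  check_signals: bool = True) -> pd.DataFrame:
    """Read and validate a cohort manifest.

    Checks required columns, numeric ages in [0, 120], supported sampling
    rates, unique subject ids and (optionally) that every referenced
    signal file exists.  Signal paths are interpreted relative to the
    manifest's directory and resolved in the returned frame.
    """
    df = read_csv(path)
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"manifest missing columns: {missing}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[ages.isna()]
    if len(bad):
        raise InputError(f"non-numeric age in manifest row(s) {list(bad)}")
    if (ages < 0).any() or (ages > 120).any():
        raise InputError("ages must lie in [0, 120] years")
    df["age"] = ages
    dupes = df["subject_id"][df["subject_id"].duplicated()].unique()
    if len(dupes):
        raise InputError(f"duplicate subject_id(s): {list(dupes)}")
    if not allow_any_rate:
        bad_rates = sorted(set(df["sampling_rate"]) - set(SUPPORTED_RATES))
        if bad_rates:
            raise InputError(f"unsupported sampling rate(s): {bad_rates}")
    base = os.path.dirname(os.path.abspath(path))
    resolved = [p if os.path.isabs(str(p)) else os.path.join(base, str(p))
                for p in df["signal_path"]]
    if check_signals:
        for sid, p in zip(df["subject_id"], resolved):
            if not os.path.exists(p):
                raise InputError(f"signal file for {sid} not found: {p}")
    df = df.copy()
    df["signal_path"] = resolved
    return df


def load_signal(path: str) -> np.ndarray:
    """Load a single-column plain-text signal file."""
    sig = np.loadtxt(path, ndmin=1)
    if sig.ndim != 1:
        raise InputError(f"signal file {path} is not single-column")
    return sig


def pulses_to_frame(pulses, ages=None) -> pd.DataFrame:
    """RepresentativePulse list -> pulses table."""
    rows = []
    for i, p in enumerate(pulses):
        row = {"subject_id": p.source_subject or f"S{i:04d}",
               "age": None if ages is None else float(ages[i]),
               "n_segments_used": p.n_segments_used,
               "median_ppi": p.median_ppi}
        row.update({f"s{j:03d}": p.samples[j] for j in range(PULSE_LENGTH)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_pulses(df: pd.DataFrame):
    """Pulses table -> (subject_ids, ages, X matrix of shape (n, 144))."""
    cols = [f"s{j:03d}" for j in range(PULSE_LENGTH)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"pulses table missing sample columns (e.g. {missing[0]})")
    X = df[cols].to_numpy(dtype=float)
    ages = df["age"].to_numpy(dtype=float) if "age" in df.columns else None
    return df["subject_id"].to_numpy(), ages, X


def screen_recordings(table: pd.DataFrame,
                      artifact_threshold: float = 0.5
                      ) -> tuple[pd.DataFrame, dict]:
    """Screen a recording inventory into the analyzable cohort.

    Recordings flagged ``device_error`` (signal loss from device
    operation failures) are excluded first; of the remainder, recordings
    whose ``artifact_fraction`` exceeds the threshold (default: more than
    50% of the trace unusable due to motion artifacts) are excluded.
    Returns the retained table and an accounting summary with keys
    n_recorded, n_device_error, n_artifact_excluded, n_analyzed.
    """
    for col in ("device_error", "artifact_fraction"):
        if col not in table.columns:
            raise InputError(f"screening table missing column {col!r}")
    n_recorded = len(table)
    ok_device = table[~table["device_error"].astype(bool)]
    n_device_error = n_recorded - len(ok_device)
    analyzed = ok_device[ok_device["artifact_fraction"] <= artifact_threshold]
    n_artifact = len(ok_device) - len(analyzed)
    accounting = {
        "n_recorded": n_recorded,
        "n_device_error": n_device_error,
        "n_artifact_excluded": n_artifact,
        "n_analyzed": len(analyzed),
    }
    return analyzed.reset_index(drop=True), accounting
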