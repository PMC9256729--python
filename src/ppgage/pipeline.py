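"""One-command pipeline: generation -> preprocessing -> cross-validation
-> Grad-CAM explanation -> evaluation.

Every stochastic stage derives its seed deterministically from the single
global seed, so a rerun with the same configuration reproduces all
artifacts byte-identically.  Artifacts land in the working directory:
``manifest.csv`` + ``signals/`` (when generating), ``pulses.csv``,
``preds.csv``, ``saliency.csv``, ``saliency_by_decade.csv``,
``report.csv``/``report.txt``, per-fold model directories under
``models/`` and a ``runlog.json``.
"""

from __future__ import annotations

import json
import os
import time
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .errors import UnusableRecordingError
from .gradcam import aggregate_by_age_group, gradcam
from .model import (ModelConfig, TrainConfig, cross_validate, save_model,
                    stratified_folds)
from .preprocess import PULSE_LENGTH, preprocess_recording
from .stats import full_report, render_report
from .synth import CohortSpec, synth_cohort, write_cohort

__all__ = ["PipelineConfig", "RunLog", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end run.

    When ``manifest`` is empty a synthetic cohort is generated from
    ``cohort`` (whose seed is derived from the global ``seed``).
    """

    workdir: str = "ppgage_run"
    manifest: str = ""
    cohort: CohortSpec = field(default_factory=CohortSpec)
    iqr_mode: str = "qd"
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    k_folds: int = 10
    val_frac: float = 0.25
    explain: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cohort = CohortSpec(**raw.pop("cohort", {}))
        model = ModelConfig(**{
            k: tuple(tuple(c) if isinstance(c, list) else c for c in v)
            if k == "conv_layers" else (tuple(v) if k == "fc_layers" else v)
            for k, v in raw.pop("model", {}).items()})
        training = TrainConfig(**raw.pop("training", {}))
        return cls(cohort=cohort, model=model, training=training, **raw)


@dataclass
class RunLog:
    """Stage timings, record counts and warnings for one pipeline run."""

    stages: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def record(self, stage: str, t0: float, n_in: int, n_out: int,
               warnings_list=()):
        self.stages.append({"stage": stage, "seconds": round(time.time() - t0, 3),
                            "n_in": int(n_in), "n_out": int(n_out),
                            "warnings": [f"{s}: {m}" for s, m in warnings_list]})

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _derive_seeds(global_seed: int, names) -> dict:
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns artifact paths and the report."""
    os.makedirs(config.workdir, exist_ok=True)
    log = RunLog()
    seeds = _derive_seeds(config.seed, ["cohort", "folds", "training"])
    log.seeds = {"global": config.seed, **seeds}
    paths = {}

    # --- cohort --------------------------------------------------------
    t0 = time.time()
    if config.manifest:
        manifest = pio.read_manifest(config.manifest)
        signals = {row.subject_id: pio.load_signal(row.signal_path)
                   for row in manifest.itertuples()}
        rates = {row.subject_id: int(row.sampling_rate)
                 for row in manifest.itertuples()}
    else:
        spec = replace(config.cohort, seed=seeds["cohort"])
        records, manifest = synth_cohort(spec)
        paths["manifest"] = write_cohort(records, manifest, config.workdir)
        manifest = pio.read_manifest(paths["manifest"])
        signals = {r.subject_id: r.signal for r in records}
        rates = {r.subject_id: r.sampling_rate for r in records}
    log.record("cohort", t0, len(manifest), len(manifest))

    # --- preprocessing -------------------------------------------------
    t0 = time.time()
    pulses, ages, kept_ids, warn_list = [], [], [], []
    age_by_id = dict(zip(manifest.subject_id, manifest.age))
    for sid in manifest.subject_id:
        try:
            pulse, stage_log = preprocess_recording(
                signals[sid], rates[sid], subject_id=sid,
                iqr_mode=config.iqr_mode)
        except UnusableRecordingError as exc:
            warn_list.append(("preprocess", f"{sid}: {exc}"))
            continue
        warn_list.extend(stage_log.warnings)
        pulses.append(pulse)
        ages.append(age_by_id[sid])
        kept_ids.append(sid)
    pulses_df = pio.pulses_to_frame(pulses, ages)
    paths["pulses"] = os.path.join(config.workdir, "pulses.csv")
    pio.write_csv(pulses_df, paths["pulses"], "pulses")
    log.record("preprocess", t0, len(manifest), len(pulses), warn_list)

    # --- cross-validation ---------------------------------------------
    t0 = time.time()
    _, ages_arr, X = pio.frame_to_pulses(pulses_df)
    plan = stratified_folds(ages_arr, k=config.k_folds,
                            val_frac=config.val_frac, seed=seeds["folds"])
    tcfg = replace(config.training, seed=seeds["training"])
    preds_df, models = cross_validate(X, ages_arr, plan,
                                      model_config=config.model,
                                      train_config=tcfg,
                                      subject_ids=np.array(kept_ids))
    paths["preds"] = os.path.join(config.workdir, "preds.csv")
    pio.write_csv(preds_df, paths["preds"], "preds")
    for fid, m in enumerate(models):
        if m is not None:
            save_model(m, os.path.join(config.workdir, "models", f"fold{fid}"))
    log.record("cross_validate", t0, len(X), len(preds_df),
               [("cross_validate", msg) for _, msg in
                preds_df.attrs.get("failures", [])])

    # --- explanation ---------------------------------------------------
    if config.explain:
        t0 = time.time()
        fold_of = {sid: int(f) for sid, f in
                   zip(preds_df.subject_id, preds_df.fold)}
        maps, map_ages, map_pulses = [], [], []
        for i, sid in enumerate(kept_ids):
            m = models[fold_of[sid]] if sid in fold_of else None
            if m is None:
                continue
            sal = gradcam(m, X[i], subject_id=sid)
            maps.append(sal)
            map_ages.append(ages_arr[i])
            map_pulses.append(X[i])
        sal_df = pd.DataFrame([{"subject_id": s.subject_id,
                                **{f"g{j:03d}": s.values[j]
                                   for j in range(PULSE_LENGTH)}}
                               for s in maps])
        paths["saliency"] = os.path.join(config.workdir, "saliency.csv")
        pio.write_csv(sal_df, paths["saliency"], "saliency")
        agg = aggregate_by_age_group(maps, map_ages, np.array(map_pulses))
        paths["saliency_by_decade"] = os.path.join(config.workdir,
                                                   "saliency_by_decade.csv")
        pio.write_csv(agg, paths["saliency_by_decade"], "saliency-by-decade")
        log.record("explain", t0, len(kept_ids), len(maps))

    # --- evaluation ----------------------------------------------------
    t0 = time.time()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = full_report(preds_df, manifest)
    paths["report"] = os.path.join(config.workdir, "report.csv")
    pio.write_csv(report, paths["report"], "report")
    with open(os.path.join(config.workdir, "report.txt"), "w") as fh:
        fh.write(render_report(report) + "\n")
    log.record("evaluate", t0, len(preds_df), len(report))

    paths["runlog"] = os.path.join(config.workdir, "runlog.json")
    log.save(paths["runlog"])
    return {"paths": paths, "report": report, "predictions": preds_df,
            "runlog": log}
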