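"""Shared fixtures: small synthetic cohorts and a tiny trained model.

Everything is generated programmatically and seeded, so the suite needs no
stored data files.
"""

import numpy as np
import pytest

from ppgage.model import ModelConfig, TrainConfig, build_model, train
from ppgage.synth import AgingMap, CohortSpec, synth_cohort, synth_recording

#: small architecture used wherever a test only needs "a CNN", not the
#: full-size default — keeps the suite fast without touching defaults
TINY_MODEL = ModelConfig(conv_layers=((4, 10, 1), (8, 8, 1)), fc_layers=(32,),
                         dropout_rate=0.0)


@pytest.fixture(scope="session")
def zero_jitter_map():
    return AgingMap().zero_jitter()


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, jitter-free, artifact-free study conditions."""
    return CohortSpec(duration=30.0, ppi_jitter_sd=0.0, noise_sd=0.0,
                      respiration_amp=0.0, artifact_rate=0.0, ectopic_rate=0.0)


@pytest.fixture(scope="session")
def clean_recording(clean_spec, zero_jitter_map):
    return synth_recording(50.0, clean_spec, seed=1, aging_map=zero_jitter_map)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 24-subject cohort with realistic noise, 30 s recordings."""
    spec = CohortSpec(n_subjects=24, duration=30.0, seed=7)
    records, manifest = synth_cohort(spec)
    return spec, records, manifest


@pytest.fixture(scope="session")
def small_pulse_dataset(small_cohort):
    """Representative pulses + ages for the small cohort."""
    from ppgage.preprocess import preprocess_recording

    _, records, _ = small_cohort
    X, ages, ids = [], [], []
    for rec in records:
        pulse, _ = preprocess_recording(rec.signal, rec.sampling_rate,
                                        subject_id=rec.subject_id)
        X.append(pulse.samples)
        ages.append(rec.age)
        ids.append(rec.subject_id)
    return np.array(X), np.array(ages), np.array(ids)


@pytest.fixture(scope="session")
def tiny_trained_model(small_pulse_dataset):
    """A small CNN trained briefly on the small cohort (for predict /
    Grad-CAM plumbing tests; not a performance fixture)."""
    X, y, _ = small_pulse_dataset
    net = build_model(TINY_MODEL, seed=3)
    cfg = TrainConfig(max_epochs=30, patience=30, batch_size=8,
                      learning_rate=1e-3, seed=3)
    return train(net, X[:18], y[:18], X[18:], y[18:], cfg,
                 model_config=TINY_MODEL)
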