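"""Grad-CAM saliency for the 1-D age regressor.

For a regression network the gradient source is the single output neuron.
With target convolutional layer activations A_k (channel k over positions)
and channel weights alpha_k equal to the positional average of
d(age)/dA_k, the raw map is ReLU(sum_k alpha_k A_k), linearly upsampled
from the conv-output length to the 144 input samples and max-normalized
to [0, 1] (an all-zero map stays zero).  Per-decade aggregation averages
maps and pulses across subjects of the same age decade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .model import TrainedAgeModel, _check_pulses
from .nn import Conv1D, Network
from .preprocess import PULSE_LENGTH

__all__ = ["SaliencyMap", "gradcam", "aggregate_by_age_group"]


@dataclass
class SaliencyMap:
    """Per-input-sample importance for one pulse: length 144, values >= 0,
    max equal to 1 unless the map is identically zero."""

    values: np.ndarray
    target_layer: int
    subject_id: str = ""

    def validate(self) -> None:
        if len(self.values) != PULSE_LENGTH:
            raise InputError(f"saliency length {len(self.values)} != {PULSE_LENGTH}")
        if self.values.min() < -1e-12:
            raise InputError("saliency values must be nonnegative")
        mx = self.values.max()
        if mx > 0 and not np.isclose(mx, 1.0):
            raise InputError("nonzero saliency map must be max-normalized")


def _conv_layer_indices(network: Network) -> list[int]:
    return [i for i, layer in enumerate(network.layers)
            if isinstance(layer, Conv1D)]


def gradcam(model: TrainedAgeModel | Network, pulse: np.ndarray,
            target_layer: int | None = None,
            subject_id: str = "") -> SaliencyMap:
    """Compute the Grad-CAM map of one 144-sample pulse.

    ``target_layer`` is an index into the network's layer stack and must
    point at a convolutional layer; by default the last one is used.
    """
    network = model.network if isinstance(model, TrainedAgeModel) else model
    conv_idx = _conv_layer_indices(network)
    if not conv_idx:
        raise ConfigurationError("network has no convolutional layer")
    if target_layer is None:
        target_layer = conv_idx[-1]
    if not isinstance(network.layers[target_layer], Conv1D):
        raise ConfigurationError(
            f"layer {target_layer} is not a convolutional layer")

    X = _check_pulses(np.asarray(pulse, dtype=float))
    if X.shape[0] != 1:
        raise InputError("gradcam expects a single pulse")
    network.forward(X[:, None, :], train=False)
    network.backward(np.ones((1, 1)))

    acts = network.layers[target_layer].last_output[0]      # (C, L)
    grads = network.output_grads[target_layer][0]           # (C, L)
    alpha = grads.mean(axis=1)                              # one weight/channel
    raw = np.maximum(alpha @ acts, 0.0)                     # (L,)

    x_old = np.linspace(0.0, 1.0, len(raw))
    x_new = np.linspace(0.0, 1.0, PULSE_LENGTH)
    values = np.interp(x_new, x_old, raw)
    mx = values.max()
    if mx > 0:
        values = values / mx
    sal = SaliencyMap(values=values, target_layer=target_layer,
                      subject_id=subject_id)
    sal.validate()
    return sal


def aggregate_by_age_group(maps: list[SaliencyMap], ages, pulses=None,
                           bin_width: int = 10) -> pd.DataFrame:
    """Mean saliency (and optionally mean pulse) per age decade.

    Returns one row per nonempty decade with columns ``decade``, ``n``,
    ``g000..g143`` and, when pulses are given, ``p000..p143``.
    """
    ages = np.asarray(ages, dtype=float)
    if len(maps) != len(ages):
        raise InputError("maps and ages must be aligned")
    if pulses is not None:
        pulses = _check_pulses(np.asarray(pulses, dtype=float))
        if len(pulses) != len(maps):
            raise InputError("pulses and maps must be aligned")
    values = np.vstack([m.values for m in maps])
    decades = (ages // bin_width).astype(int) * bin_width
    rows = []
    for dec in np.unique(decades):
        mask = decades == dec
        row = {"decade": int(dec), "n": int(mask.sum())}
        mean_map = values[mask].mean(axis=0)
        row.update({f"g{i:03d}": mean_map[i] for i in range(PULSE_LENGTH)})
        if pulses is not None:
            mean_pulse = pulses[mask].mean(axis=0)
            row.update({f"p{i:03d}": mean_pulse[i] for i in range(PULSE_LENGTH)})
        rows.append(row)
    return pd.DataFrame(rows)
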