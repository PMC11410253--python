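"""Cross-layer connectivity attribution and V1 filter characterization.

For a target unit (e.g. one IT unit), the contribution of each input
channel (e.g. the 256 V4 channels) is estimated as the product of

* the summed kernel weights of the 3x3 convolution filter connecting the
  input channel to the target channel (summation rather than a norm,
  because rectified inputs are nonnegative — negative weights can only
  dampen the response), and
* the channel's "drive": the maximum response, over the target's
  20-stimulus factorial probe set, of any word-selective input unit of
  that channel lying inside the target's effective receptive field.

Positive products mark excitatory channels, negative products inhibitory
ones.  The identical code path serves any adjacent layer pair (V4->IT,
V2->V4, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cornet import CORnetZ, effective_receptive_field
from .stimgen import ProbeDesign
from .store import ActivationStore, UnitAddress


@dataclass
class ConnectivityReport:
    target: UnitAddress
    input_layer: str
    weight_sums: np.ndarray  # (n_input_channels,)
    drive: np.ndarray  # (n_input_channels,)
    product: np.ndarray
    no_unit_in_rf: np.ndarray  # bool flag per channel
    top_excitatory: list[int]
    top_inhibitory: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": np.arange(len(self.weight_sums)),
            "weight_sum": self.weight_sums,
            "drive": self.drive,
            "product": self.product,
            "no_unit_in_rf": self.no_unit_in_rf,
        })


def filter_weight_sums(model: CORnetZ, target_layer: str,
                       target_channel: int) -> np.ndarray:
    """Per-input-channel sum of the target channel's kernel weights."""
    try:
        w = model.conv_weights(target_layer)
    except KeyError:
        raise ValueError(f"{target_layer!r} has no convolutional input "
                         "weights") from None
    return w[target_channel].sum(axis=(1, 2)).astype(np.float64)


def channel_drive(target: UnitAddress, input_store: ActivationStore,
                  word_selective_mask: np.ndarray, model_or_spec,
                  input_layer: str | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-input-channel drive inside the target's effective RF.

    ``input_store`` holds the input layer's responses to the target's
    factorial probe stimuli; ``word_selective_mask`` is a boolean
    (channels, rows, cols) array marking word-selective input units.
    Channels with no word-selective unit inside the RF get drive 0 and a
    flag.  Returns (drive, no_unit_in_rf).
    """
    if input_layer is None:
        if len(input_store.layers) != 1:
            raise ValueError("input_layer required for a multi-layer store")
        input_layer = next(iter(input_store.layers))
    acts = input_store.get(input_layer)  # (n_stim, C, H, W)
    if acts.ndim != 4:
        raise ValueError(f"input layer {input_layer!r} must be spatial")
    if acts.shape[0] == 0:
        raise ValueError("empty probe store")
    n_stim, n_ch, h, w = acts.shape
    mask = np.asarray(word_selective_mask, dtype=bool)
    if mask.shape != (n_ch, h, w):
        raise ValueError(
            f"selectivity mask shape {mask.shape} does not match input "
            f"layer grid {(n_ch, h, w)}"
        )
    r0, r1, c0, c1 = effective_receptive_field(model_or_spec, target,
                                               input_layer)
    peak = acts.max(axis=0)  # (C, H, W): max over the probe stimuli
    region = peak[:, r0:r1 + 1, c0:c1 + 1]
    region_mask = mask[:, r0:r1 + 1, c0:c1 + 1]
    drive = np.where(region_mask, region, -np.inf).reshape(n_ch, -1).max(axis=1)
    no_unit = ~region_mask.reshape(n_ch, -1).any(axis=1)
    drive = np.where(no_unit, 0.0, drive)
    return drive.astype(np.float64), no_unit


def attribute(model: CORnetZ, target: UnitAddress, input_layer: str,
              input_store: ActivationStore,
              word_selective_mask: np.ndarray,
              probe_design: ProbeDesign | None = None,
              top_k: int = 2) -> ConnectivityReport:
    """Rank input channels by weight-sum x drive for one target unit.

    ``input_store`` must be recorded on the target's factorial probe set
    (20 stimuli built from its best/worst letters).  ``probe_design`` is
    accepted for provenance checking only.
    """
    if probe_design is not None:
        expected = probe_design.n_rows * probe_design.n_cols
        if input_store.n_stimuli != expected:
            raise ValueError(
                f"store has {input_store.n_stimuli} stimuli but the probe "
                f"design has {expected}"
            )
    wsum = filter_weight_sums(model, target.layer, target.channel)
    drive, no_unit = channel_drive(target, input_store,
                                   word_selective_mask, model, input_layer)
    product = wsum * drive
    if np.all(drive == 0):
        exc, inh = [], []
    else:
        order = np.argsort(product)
        exc = [int(i) for i in order[::-1][:top_k] if product[i] > 0]
        inh = [int(i) for i in order[:top_k] if product[i] < 0]
    return ConnectivityReport(
        target=target, input_layer=input_layer, weight_sums=wsum,
        drive=drive, product=product, no_unit_in_rf=no_unit,
        top_excitatory=exc, top_inhibitory=inh,
    )


# --------------------------------------------------------------------------
# V1 spatial-frequency characterization


def v1_filter_spectrum(model: CORnetZ, block: str = "V1") -> pd.DataFrame:
    """Peak radial spatial frequency of each first-layer filter.

    Each kernel's 2-D Fourier amplitude spectrum is summed over input
    channels; the peak radial frequency (cycles/pixel, DC included)
    classifies the filter as "low" or "high" by a median split across
    filters.
    """
    w = model.conv_weights(block)  # (out, in, k, k)
    peaks = kernel_peak_frequencies(w)
    median = float(np.median(peaks))
    return pd.DataFrame({
        "channel": np.arange(len(peaks)),
        "peak_frequency": peaks,
        "class": np.where(peaks > median, "high", "low"),
    })


def kernel_peak_frequencies(kernels: np.ndarray) -> np.ndarray:
    """(out, in, k, k) kernels -> peak radial frequency per output filter."""
    out_ch, _, k, _ = kernels.shape
    f = np.fft.fftfreq(k)
    radial = np.hypot(f[:, None], f[None, :])
    peaks = np.empty(out_ch)
    for i in range(out_ch):
        amp = np.abs(np.fft.fft2(kernels[i])).sum(axis=0)
        peaks[i] = radial.flat[int(amp.argmax())]
    return peaks
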