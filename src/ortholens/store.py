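"""Per-stimulus activation storage and unit addressing."""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np


@dataclass(frozen=True, order=True)
class UnitAddress:
    """Address of one unit: layer name, channel, and (for convolutional
    layers) the spatial grid position.  Indices are 0-based internally;
    human-facing reports print them 1-based."""

    layer: str
    channel: int
    row: int | None = None
    col: int | None = None

    @property
    def spatial(self) -> bool:
        return self.row is not None

    def flat_index(self, rows: int, cols: int) -> int:
        if not self.spatial:
            return self.channel
        return (self.channel * rows + self.row) * cols + self.col

    def __str__(self) -> str:  # 1-based, e.g. "V4:12:3:7"
        if self.spatial:
            return f"{self.layer}:{self.channel + 1}:{self.row + 1}:{self.col + 1}"
        return f"{self.layer}:{self.channel + 1}"


class ActivationStore:
    """Recorded activations keyed by layer name.

    Convolutional layers are stored as (n_stimuli, channels, rows, cols);
    vector layers (avgIT, output) as (n_stimuli, channels).
    """

    def __init__(self, layers: dict[str, np.ndarray],
                 stimulus_ids: list[str] | None = None):
        ns = {a.shape[0] for a in layers.values()}
        if len(ns) > 1:
            raise ValueError(f"inconsistent stimulus counts: {ns}")
        self.layers = dict(layers)
        self.n_stimuli = next(iter(ns)) if ns else 0
        self.stimulus_ids = (list(stimulus_ids) if stimulus_ids is not None
                             else [str(i) for i in range(self.n_stimuli)])

    def __contains__(self, layer: str) -> bool:
        return layer in self.layers

    def get(self, layer: str) -> np.ndarray:
        try:
            return self.layers[layer]
        except KeyError:
            raise KeyError(
                f"layer {layer!r} not recorded; have {sorted(self.layers)}"
            ) from None

    def unit_responses(self, unit: UnitAddress) -> np.ndarray:
        """Length-n_stimuli response vector of one unit."""
        a = self.get(unit.layer)
        if unit.spatial:
            if a.ndim != 4:
                raise ValueError(f"layer {unit.layer!r} is not spatial")
            return a[:, unit.channel, unit.row, unit.col]
        if a.ndim == 4:
            raise ValueError(f"layer {unit.layer!r} needs a spatial address")
        return a[:, unit.channel]

    def flat(self, layer: str) -> np.ndarray:
        """(n_stimuli, n_units) view with units flattened C-order."""
        a = self.get(layer)
        return a.reshape(a.shape[0], -1)

    def unit_addresses(self, layer: str) -> list[UnitAddress]:
        """All unit addresses of a layer in flat C-order."""
        a = self.get(layer)
        if a.ndim == 2:
            return [UnitAddress(layer, ch) for ch in range(a.shape[1])]
        _, c, r, w = a.shape
        return [UnitAddress(layer, ch, i, j)
                for ch in range(c) for i in range(r) for j in range(w)]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "stimulus_ids",
                data=np.array(self.stimulus_ids, dtype=h5py.string_dtype()))
            g = f.create_group("layers")
            for name, arr in self.layers.items():
                g.create_dataset(name, data=arr, compression="gzip")

    @classmethod
    def load(cls, path) -> "ActivationStore":
        with h5py.File(path, "r") as f:
            ids = [s.decode() for s in f["stimulus_ids"][...]]
            layers = {k: v[...] for k, v in f["layers"].items()}
        return cls(layers, ids)
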