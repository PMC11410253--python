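"""CORnet-Z-style ventral-stream model: architecture, two-phase literacy
training, activation recording, and receptive-field backprojection.

The network is four blocks named after ventral visual areas (V1, V2, V4,
IT), each block being convolution -> rectification -> max-pooling,
followed by a global average pool ("avgIT") and a fully connected
readout.  With the default widths (64, 128, 256, 512) and a 224x224x3
input the block outputs are V1 64x56x56, V2 128x28x28, V4 256x14x14 and
IT 512x7x7.

Training mimics literacy acquisition in two phases: phase 1 on object
categories alone (the "illiterate" network), then the readout is
extended with word categories and the whole network is retrained jointly
on objects plus words (the "literate" network).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .store import ActivationStore, UnitAddress

LAYER_ORDER = ("V1", "V2", "V4", "IT", "avgIT", "output")

#: input normalisation applied to every image before the forward pass
INPUT_MEAN = 0.5
INPUT_STD = 0.25


@dataclass(frozen=True)
class BlockSpec:
    name: str
    out_channels: int
    conv_kernel: int
    conv_stride: int
    pool_kernel: int = 3
    pool_stride: int = 2


@dataclass(frozen=True)
class NetworkSpec:
    blocks: tuple[BlockSpec, ...]
    input_size: int = 224
    in_channels: int = 3

    def block(self, name: str) -> BlockSpec:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def block_index(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if b.name == name:
                return i
        raise KeyError(f"no block named {name!r}")

    def grid_sizes(self) -> dict[str, tuple[int, int]]:
        """(post-conv, post-pool) spatial size per block."""
        sizes = {}
        n = self.input_size
        for b in self.blocks:
            n_conv = nn.conv_out_size(n, b.conv_kernel, b.conv_stride,
                                      b.conv_kernel // 2)
            n_pool = nn.conv_out_size(n_conv, b.pool_kernel, b.pool_stride, 1)
            if n_pool < 1:
                raise ValueError(
                    f"block {b.name!r} collapses the grid "
                    f"(input {n}, conv->{n_conv}, pool->{n_pool})"
                )
            sizes[b.name] = (n_conv, n_pool)
            n = n_pool
        return sizes


def default_spec(input_size: int = 224,
                 widths: tuple[int, int, int, int] = (64, 128, 256, 512)
                 ) -> NetworkSpec:
    """Standard four-block architecture; V1 uses a 7x7 stride-2 kernel,
    later blocks 3x3 stride-1, all pooled 3x3 stride 2."""
    names = ("V1", "V2", "V4", "IT")
    blocks = tuple(
        BlockSpec(name, w, conv_kernel=7 if name == "V1" else 3,
                  conv_stride=2 if name == "V1" else 1)
        for name, w in zip(names, widths)
    )
    return NetworkSpec(blocks=blocks, input_size=input_size)


@dataclass
class TrainingSchedule:
    """SGD on categorical cross-entropy; learning rate decays by
    ``lr_gamma`` every ``lr_step`` epochs (step schedule)."""

    epochs: int
    lr0: float = 0.01
    lr_step: int = 10
    lr_gamma: float = 0.1
    momentum: float = 0.9
    batch_size: int = 32

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.lr_gamma ** (epoch // self.lr_step)


class CORnetZ:
    """Feedforward model instance; see :func:`build_network`."""

    def __init__(self, spec: NetworkSpec, n_out: int,
                 rng: np.random.Generator):
        spec.grid_sizes()  # validates geometry, raises naming the block
        self.spec = spec
        self.n_out = n_out
        self.block_layers: dict[str, tuple[nn.Conv2d, nn.ReLU, nn.MaxPool2d]] = {}
        in_ch = spec.in_channels
        seq: list[nn.Layer] = []
        for b in spec.blocks:
            conv = nn.Conv2d(in_ch, b.out_channels, b.conv_kernel,
                             b.conv_stride, b.conv_kernel // 2, rng)
            relu, pool = nn.ReLU(), nn.MaxPool2d(b.pool_kernel, b.pool_stride, 1)
            self.block_layers[b.name] = (conv, relu, pool)
            seq += [conv, relu, pool]
            in_ch = b.out_channels
        self.avgpool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_ch, n_out, rng)
        self._seq = seq
        seq[0].needs_dx = False  # input gradient is never consumed

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                record: tuple[str, ...] | None = None
                ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Forward pass on normalised NCHW input.

        ``record`` selects layer outputs to return: block names give the
        post-rectification, post-pooling block output; "avgIT" the
        channel-wise spatial mean of IT; "output" the logits.
        """
        record = tuple(record or ())
        unknown = set(record) - set(LAYER_ORDER)
        if unknown:
            raise KeyError(f"unknown layer(s) {sorted(unknown)}; "
                           f"valid: {LAYER_ORDER}")
        acts: dict[str, np.ndarray] = {}
        h = x
        for b in self.spec.blocks:
            conv, relu, pool = self.block_layers[b.name]
            h = pool.forward(relu.forward(conv.forward(h, train), train), train)
            if b.name in record:
                acts[b.name] = h
        v = self.avgpool.forward(h, train)
        if "avgIT" in record:
            acts["avgIT"] = v
        logits = self.fc.forward(v, train)
        if "output" in record:
            acts["output"] = logits
        return logits, acts

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.fc.backward(dlogits)
        dy = self.avgpool.backward(dy)
        for layer in reversed(self._seq):
            dy = layer.backward(dy)

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._seq:
            out += layer.params()
        return out + self.fc.params()

    def conv_weights(self, block: str) -> np.ndarray:
        """(out_ch, in_ch, k, k) convolution kernel of a block."""
        return self.block_layers[block][0].W.value

    def copy(self) -> "CORnetZ":
        return copy.deepcopy(self)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint spec + weights as a compressed npz archive."""
        import json

        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        meta = {
            "input_size": self.spec.input_size,
            "in_channels": self.spec.in_channels,
            "n_out": self.n_out,
            "blocks": [[b.name, b.out_channels, b.conv_kernel, b.conv_stride,
                        b.pool_kernel, b.pool_stride]
                       for b in self.spec.blocks],
        }
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "CORnetZ":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            spec = NetworkSpec(
                blocks=tuple(BlockSpec(*b) for b in meta["blocks"]),
                input_size=meta["input_size"],
                in_channels=meta["in_channels"],
            )
            model = cls(spec, meta["n_out"], np.random.default_rng(0))
            for i, p in enumerate(model.params()):
                loaded = data[f"param_{i}"]
                if loaded.shape != p.value.shape:
                    raise ValueError(
                        f"checkpoint parameter {i} has shape {loaded.shape}, "
                        f"expected {p.value.shape}"
                    )
                p.value[...] = loaded
        return model


def build_network(spec: NetworkSpec, n_out: int, seed: int = 0) -> CORnetZ:
    """Instantiate a seeded model; raises if the spec geometry is invalid."""
    return CORnetZ(spec, n_out, np.random.default_rng(seed))


def extend_output(model: CORnetZ, n_new_categories: int,
                  seed: int = 0, init_scale: float = 1e-3) -> CORnetZ:
    """Add output categories with full connectivity to avgIT.

    Returns a new model; the original is untouched.  Existing readout
    rows are preserved exactly and new rows get small zero-mean weights,
    so pre-existing logits are unchanged immediately after extension.
    """
    if n_new_categories <= 0:
        raise ValueError("n_new_categories must be positive")
    rng = np.random.default_rng(seed)
    new = model.copy()
    old_w, old_b = new.fc.W.value, new.fc.b.value
    extra = rng.normal(0.0, init_scale,
                       size=(n_new_categories, old_w.shape[1])
                       ).astype(np.float32)
    new.fc.W = nn.Param(np.vstack([old_w, extra]))
    new.fc.b = nn.Param(np.concatenate(
        [old_b, np.zeros(n_new_categories, dtype=np.float32)]))
    new.n_out = old_w.shape[0] + n_new_categories
    return new


# --------------------------------------------------------------------------
# input preparation and augmentation


def to_input(images: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) [0,1] images -> normalised float32 NCHW."""
    x = np.transpose(images, (0, 3, 1, 2)).astype(np.float32)
    return (x - INPUT_MEAN) / INPUT_STD


def random_resized_crop(image: np.ndarray, rng: np.random.Generator,
                        min_retain: float = 0.9) -> np.ndarray:
    """Crop a random box retaining >= ``min_retain`` of the area, then
    resize back to the original shape.  No flips (mirror words are not
    legal stimuli)."""
    h, w, _ = image.shape
    frac = float(rng.uniform(np.sqrt(min_retain), 1.0))
    ch, cw = max(1, int(round(h * frac))), max(1, int(round(w * frac)))
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    crop = image[top:top + ch, left:left + cw, 0]
    img = Image.fromarray((crop * 255).astype(np.uint8))
    out = np.asarray(img.resize((w, h), Image.BILINEAR),
                     dtype=np.float32) / 255.0
    return np.repeat(out[:, :, None], 3, axis=2)


# --------------------------------------------------------------------------
# training


def train(model: CORnetZ, data: dict[str, tuple[np.ndarray, np.ndarray]],
          schedule: TrainingSchedule, seed: int = 0,
          eval_data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
          augment: bool = True, min_retain: float = 0.9) -> pd.DataFrame:
    """Train in place with SGD; returns a per-epoch metrics log.

    ``data`` maps a domain name (e.g. "objects", "words") to
    ``(images (N,H,W,3), integer labels)``; domains are concatenated and
    shuffled jointly each epoch.  ``eval_data`` domains are scored for
    top-1 accuracy after every epoch.  Reproducible given the seed.
    """
    if not data or any(len(v[0]) == 0 for v in data.values()):
        raise ValueError("empty training dataset")
    images = np.concatenate([v[0] for v in data.values()])
    labels = np.concatenate([np.asarray(v[1], dtype=np.int64)
                             for v in data.values()])
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.params(), lr=schedule.lr0, momentum=schedule.momentum)
    log = []
    for epoch in range(schedule.epochs):
        opt.lr = schedule.lr_at(epoch)
        order = rng.permutation(len(images))
        losses = []
        for start in range(0, len(order), schedule.batch_size):
            idx = order[start:start + schedule.batch_size]
            batch = images[idx]
            if augment:
                batch = np.stack([
                    random_resized_crop(im, rng, min_retain) for im in batch
                ])
            x = to_input(batch)
            logits, _ = model.forward(x, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch + 1, "lr": opt.lr,
               "loss": float(np.mean(losses))}
        for name, (im, lab) in (eval_data or {}).items():
            row[f"acc_{name}"] = evaluate(model, im, lab)
        log.append(row)
    return pd.DataFrame(log)


def evaluate(model: CORnetZ, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> float:
    """Top-1 accuracy on (N,H,W,3) images with integer labels."""
    correct = 0
    for start in range(0, len(images), batch_size):
        x = to_input(images[start:start + batch_size])
        logits, _ = model.forward(x)
        correct += int((logits.argmax(axis=1)
                        == labels[start:start + batch_size]).sum())
    return correct / len(images)


# --------------------------------------------------------------------------
# activation recording


def record_activations(model: CORnetZ, stimuli, layers,
                       batch_size: int = 64) -> ActivationStore:
    """Run stimuli through the model and store the requested layers.

    ``stimuli`` is a list of rendered stimuli or an (N,H,W,3) array at
    the model's canvas size.  Block entries are post-rectification,
    post-pooling outputs; "avgIT" is the spatial mean of IT.
    """
    layers = tuple(layers)
    if hasattr(stimuli, "ndim"):
        images = stimuli
        ids = [str(i) for i in range(len(images))]
    else:
        images = np.stack([s.image for s in stimuli])
        ids = [s.text or str(i) for i, s in enumerate(stimuli)]
    expected = model.spec.input_size
    if images.shape[1] != expected:
        raise ValueError(
            f"stimuli are {images.shape[1]}px but the model expects "
            f"{expected}px"
        )
    chunks: dict[str, list[np.ndarray]] = {l: [] for l in layers}
    for start in range(0, len(images), batch_size):
        x = to_input(images[start:start + batch_size])
        _, acts = model.forward(x, record=layers)
        for l in layers:
            chunks[l].append(acts[l])
    return ActivationStore(
        {l: np.concatenate(chunks[l]) for l in layers}, ids)


# --------------------------------------------------------------------------
# receptive-field backprojection


def effective_receptive_field(model_or_spec, unit: UnitAddress,
                              to_layer: str) -> tuple[int, int, int, int]:
    """Exact backprojection of one unit onto an earlier layer's grid.

    Returns the inclusive bounding box (row0, row1, col0, col1) of the
    positions on ``to_layer``'s post-pool output grid that can influence
    the unit, clipped at the grid borders.  A central IT unit projects to
    a 5x5 box on V4 (3x3 pool window followed by a padded 3x3
    convolution); a unit projected onto its own layer is 1x1.
    """
    spec: NetworkSpec = getattr(model_or_spec, "spec", model_or_spec)
    sizes = spec.grid_sizes()
    if to_layer not in sizes:
        raise KeyError(f"unknown target layer {to_layer!r}")
    if unit.layer == "avgIT":
        n = sizes[to_layer][1]
        return (0, n - 1, 0, n - 1)
    i_from = spec.block_index(unit.layer)
    i_to = spec.block_index(to_layer)
    if i_to > i_from:
        raise ValueError(
            f"{to_layer} is later than {unit.layer}; backprojection runs "
            "toward the input"
        )
    if unit.row is None or unit.col is None:
        raise ValueError("convolutional unit address needs row/col")
    rows = (unit.row, unit.row)
    cols = (unit.col, unit.col)
    for i in range(i_from, i_to, -1):
        b = spec.blocks[i]
        prev_pool = sizes[spec.blocks[i - 1].name][1]
        n_conv = sizes[b.name][0]
        # invert the pool: output grid -> conv grid
        rows = _backproject_interval(rows, b.pool_kernel, b.pool_stride, 1,
                                     n_conv)
        cols = _backproject_interval(cols, b.pool_kernel, b.pool_stride, 1,
                                     n_conv)
        # invert the convolution: conv grid -> previous block's output grid
        p = b.conv_kernel // 2
        rows = _backproject_interval(rows, b.conv_kernel, b.conv_stride, p,
                                     prev_pool)
        cols = _backproject_interval(cols, b.conv_kernel, b.conv_stride, p,
                                     prev_pool)
    return (rows[0], rows[1], cols[0], cols[1])


def _backproject_interval(iv: tuple[int, int], k: int, s: int, p: int,
                          in_size: int) -> tuple[int, int]:
    lo = iv[0] * s - p
    hi = iv[1] * s - p + k - 1
    return (max(lo, 0), min(hi, in_size - 1))


def rf_box_side(box: tuple[int, int, int, int]) -> int:
    """Side of the (square) bounding box; max of the two extents."""
    return max(box[1] - box[0] + 1, box[3] - box[2] + 1)
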