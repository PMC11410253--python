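"""Synthetic unit populations with planted, symbolically defined tuning.

Each synthetic unit's response is a pure function of a stimulus's
symbolic slot layout (glyph per slot, '-' = blank) — never of pixels —
so every analysis stage can be validated against known ground truth
without training a network.  Supported tuning kinds:

* ``retinotopic``      — letter at a fixed slot, gaussian falloff over slots;
* ``ordinal_start``    — preferred letter at ordinal position k from the
                         word's first letter, any slot (optionally gated
                         by a retinotopic window);
* ``ordinal_end``      — k counted from the word's last letter;
* ``space_bigram_left``  — preferred letter with a blank (or the frame
                           edge) immediately to its left, inside a
                           retinotopic window;
* ``space_bigram_right`` — blank immediately right;
* ``letter_invariant`` — preferred letter anywhere;
* ``word_position``    — word (first non-blank slot) starting at a fixed slot;
* ``mixed``            — weighted sum of two component specs.

Gaussian noise (truncated at zero, mimicking rectified activations) is
added on top of the deterministic response.  All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimgen import BLANK
from .store import ActivationStore

KINDS = ("retinotopic", "ordinal_start", "ordinal_end", "space_bigram_left",
         "space_bigram_right", "letter_invariant", "word_position", "mixed")


@dataclass
class SyntheticUnitSpec:
    kind: str
    preferred_letters: dict[str, float] = field(default_factory=dict)
    position_param: int = 0  # slot (retinotopic/word_position) or ordinal k
    rf: tuple[int, int] | None = None  # inclusive retinotopic slot window
    tuning_width: float = 0.7  # slots; gaussian falloff (retinotopic)
    gain: float = 10.0  # comfortably above the default exclusion threshold
    noise_sd: float = 0.0
    components: tuple = ()  # for kind="mixed": ((spec, weight), ...)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def weight(self, glyph: str) -> float:
        return self.preferred_letters.get(glyph, 0.0)

    def in_rf(self, slot: int) -> bool:
        return self.rf is None or self.rf[0] <= slot <= self.rf[1]


def _letters(slots: tuple[str, ...]) -> list[tuple[int, str]]:
    return [(i, g) for i, g in enumerate(slots) if g != BLANK]


def _noiseless(spec: SyntheticUnitSpec, slots: tuple[str, ...]) -> float:
    letters = _letters(slots)
    k = spec.kind
    if k == "retinotopic":
        return spec.gain * sum(
            spec.weight(g) * np.exp(-0.5 * ((s - spec.position_param)
                                            / spec.tuning_width) ** 2)
            for s, g in letters
        )
    if k in ("ordinal_start", "ordinal_end"):
        if not letters:
            return 0.0
        idx = spec.position_param if k == "ordinal_start" \
            else len(letters) - 1 - spec.position_param
        if not 0 <= idx < len(letters):
            return 0.0
        slot, glyph = letters[idx]
        if not spec.in_rf(slot):
            return 0.0
        return spec.gain * spec.weight(glyph)
    if k in ("space_bigram_left", "space_bigram_right"):
        best = 0.0
        n = len(slots)
        for s, g in letters:
            if not spec.in_rf(s):
                continue
            if k == "space_bigram_left":
                open_side = s == 0 or slots[s - 1] == BLANK
            else:
                open_side = s == n - 1 or slots[s + 1] == BLANK
            if open_side:
                best = max(best, spec.gain * spec.weight(g))
        return best
    if k == "letter_invariant":
        return spec.gain * max((spec.weight(g) for _, g in letters),
                               default=0.0)
    if k == "word_position":
        if not letters:
            return 0.0
        return spec.gain if letters[0][0] == spec.position_param else 0.0
    if k == "mixed":
        return sum(w * _noiseless(sub, slots) for sub, w in spec.components)
    raise AssertionError(k)


def respond(spec: SyntheticUnitSpec, stimulus_metadata,
            rng: np.random.Generator | None = None) -> float:
    """Response of one synthetic unit to one stimulus.

    ``stimulus_metadata`` is a slot layout tuple or an object with a
    ``slots`` attribute (e.g. a rendered probe stimulus).  Noise is drawn
    from the supplied generator; with ``noise_sd = 0`` the response is
    fully deterministic.
    """
    slots = getattr(stimulus_metadata, "slots", stimulus_metadata)
    if slots is None:
        raise ValueError("stimulus metadata lacks a slot layout")
    value = _noiseless(spec, tuple(slots))
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        value += float(rng.normal(0.0, spec.noise_sd))
    return max(value, 0.0)


def generate_population(specs: list[SyntheticUnitSpec],
                        designs: dict[str, list],
                        layer: str = "synth",
                        seed: int = 0
                        ) -> tuple[dict[str, ActivationStore], pd.DataFrame]:
    """Response stores for a unit population over named stimulus sets.

    ``designs`` maps a set name to a list of slot layouts (or objects
    carrying ``.slots``).  Returns one ActivationStore per set, shaped
    (n_stimuli, n_units) under ``layer``, plus a sidecar ground-truth
    table (unit index, kind, parameters).
    """
    rng = np.random.default_rng(seed)
    stores = {}
    for name, stimuli in designs.items():
        resp = np.empty((len(stimuli), len(specs)), dtype=np.float32)
        for j, spec in enumerate(specs):
            for i, stim in enumerate(stimuli):
                resp[i, j] = respond(spec, stim, rng)
        stores[name] = ActivationStore({layer: resp})
    truth = pd.DataFrame([
        {"unit": j, "kind": s.kind, "position_param": s.position_param,
         "rf": s.rf, "gain": s.gain, "noise_sd": s.noise_sd,
         "preferred": "".join(sorted(s.preferred_letters))}
        for j, s in enumerate(specs)
    ])
    return stores, truth


def sample_population(n_units: int, mixture: dict[str, float],
                      preferred: str, seed: int = 0,
                      noise_sd: float = 0.0, gain: float = 10.0,
                      frame_slots: int = 8) -> list[SyntheticUnitSpec]:
    """Random population over tuning kinds with given mixture weights.

    All units prefer the same letter (so a single probe design applies);
    per-unit position parameters and receptive fields are drawn
    uniformly over valid values.
    """
    rng = np.random.default_rng(seed)
    kinds = list(mixture)
    probs = np.array([mixture[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    specs = []
    for _ in range(n_units):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        spec = _sample_one(kind, preferred, rng, noise_sd, gain, frame_slots)
        specs.append(spec)
    return specs


def _sample_one(kind: str, preferred: str, rng: np.random.Generator,
                noise_sd: float, gain: float,
                frame_slots: int) -> SyntheticUnitSpec:
    letters = {preferred: 1.0}
    if kind == "retinotopic":
        # central slots: the 5x4 probe design covers slots 2-5 with
        # diagonal runs long enough to classify
        return SyntheticUnitSpec(
            kind=kind, preferred_letters=letters,
            position_param=int(rng.integers(2, 6)),
            tuning_width=float(rng.uniform(0.4, 0.8)),
            gain=gain, noise_sd=noise_sd,
        )
    if kind in ("ordinal_start", "ordinal_end"):
        return SyntheticUnitSpec(
            kind=kind, preferred_letters=letters,
            position_param=int(rng.integers(3)),
            gain=gain, noise_sd=noise_sd,
        )
    if kind in ("space_bigram_left", "space_bigram_right"):
        # RF slots where both probe designs place the relevant word edge
        lo = int(rng.integers(2, 5)) if kind.endswith("left") \
            else int(rng.integers(3, 6))
        return SyntheticUnitSpec(
            kind=kind, preferred_letters=letters, rf=(lo, lo),
            gain=gain, noise_sd=noise_sd,
        )
    if kind == "letter_invariant":
        return SyntheticUnitSpec(kind=kind, preferred_letters=letters,
                                 gain=gain, noise_sd=noise_sd)
    if kind == "word_position":
        return SyntheticUnitSpec(
            kind=kind, preferred_letters=letters,
            position_param=int(rng.integers(frame_slots - 3)),
            gain=gain, noise_sd=noise_sd,
        )
    raise ValueError(f"cannot sample kind {kind!r}")
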