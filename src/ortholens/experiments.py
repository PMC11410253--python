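"""Desk-scale literacy experiment: train a literate and an illiterate
network and run the full probing suite on both.

This is a deliberately scaled-down emulation of the full-scale regime
(ImageNet-sized object training, 1000 words, 224-px canvas): a 64-px
canvas, 20 words x 200 variants, four procedural object categories and
a narrow network.  It is meant to reproduce the qualitative signatures
of literacy — more word-selective units, higher bigram dissimilarity
from V4 on, and the appearance of ordinal-position units in late layers
— not the full-scale percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import profiles as prof
from . import rdm, selectivity, stimgen
from .cornet import (CORnetZ, TrainingSchedule, build_network, default_spec,
                     extend_output, record_activations, train)
from .lexicon import ALPHABET, default_words
from .objects import CATEGORIES, make_object_set
from .stimgen import DEFAULT_CANVAS, CanvasConfig, make_bigram_set
from .store import ActivationStore, UnitAddress

PROBE_LAYERS = ("V1", "V2", "V4", "IT", "avgIT")
LATE_LAYERS = ("IT", "avgIT")


@dataclass(frozen=True)
class ScaledProfile:
    """Study conditions for the desk-scale experiment."""

    canvas_size: int = 64
    widths: tuple[int, int, int, int] = (24, 48, 96, 192)
    n_words: int = 20
    n_train_per_word: int = 200
    n_test_per_word: int = 10
    n_objects_per_category: int = 200
    n_object_test_per_category: int = 40
    epochs_phase1: int = 4
    epochs_phase2: int = 12
    batch_size: int = 32
    localizer_words: int = 400
    localizer_per_category: int = 100
    n_bigrams: int = 49
    k_sd: float = 3.0
    #: exclusion threshold for response-profile analysis, in this
    #: network's activation units (narrower net, smaller activations)
    exclusion: float = 0.1
    max_profile_units: int = 40  # per layer, keeps probing affordable

    @property
    def canvas(self) -> CanvasConfig:
        return DEFAULT_CANVAS.scaled(self.canvas_size)


@dataclass
class EmergenceResult:
    seed: int
    profile: ScaledProfile
    word_test_acc: float
    object_test_acc: dict[str, float]  # per network
    train_log: dict[str, pd.DataFrame]
    n_selective: dict[str, dict[str, int]]  # network -> layer -> count
    mean_d: dict[str, dict[str, float]]  # network -> layer -> mean 1-r
    category_counts: dict[str, dict[str, int]]  # layer -> category -> n
    ordinal_fraction_late: float
    n_space_bigram_late: int


def train_pair(profile: ScaledProfile, seed: int
               ) -> tuple[CORnetZ, CORnetZ, dict]:
    """Phase-1 object training, then literate/illiterate continuation.

    Returns (literate, illiterate, info).  Both networks share the same
    phase-1 weights; the literate one is retrained jointly on objects
    plus words after output extension, the illiterate one continues on
    objects alone for the same number of epochs.
    """
    canvas = profile.canvas
    words = default_words(profile.n_words)
    train_ds, test_ds = stimgen.make_training_set(
        words, profile.n_train_per_word, profile.n_test_per_word,
        seed=seed, canvas=canvas)
    word_images = train_ds.images()
    word_labels = np.array([words.index(w) for w in train_ds.labels])
    word_test_images = test_ds.images()
    word_test_labels = np.array([words.index(w) for w in test_ds.labels])

    n_cats = len(CATEGORIES)
    obj_images, obj_cats = make_object_set(
        profile.n_objects_per_category, seed + 1, canvas.size)
    obj_labels = np.array([CATEGORIES.index(c) for c in obj_cats])
    obj_test_images, obj_test_cats = make_object_set(
        profile.n_object_test_per_category, seed + 2, canvas.size)
    obj_test_labels = np.array([CATEGORIES.index(c) for c in obj_test_cats])

    spec = default_spec(canvas.size, profile.widths)
    base = build_network(spec, n_out=n_cats, seed=seed)
    sched1 = TrainingSchedule(epochs=profile.epochs_phase1,
                              batch_size=profile.batch_size)
    log1 = train(base, {"objects": (obj_images, obj_labels)}, sched1,
                 seed=seed,
                 eval_data={"objects": (obj_test_images, obj_test_labels)})

    literate = extend_output(base, profile.n_words, seed=seed)
    sched2 = TrainingSchedule(epochs=profile.epochs_phase2,
                              batch_size=profile.batch_size)
    log2 = train(
        literate,
        {"objects": (obj_images, obj_labels),
         "words": (word_images, word_labels + n_cats)},
        sched2, seed=seed + 10,
        eval_data={"objects": (obj_test_images, obj_test_labels),
                   "words": (word_test_images, word_test_labels + n_cats)},
    )

    illiterate = base.copy()
    log3 = train(illiterate, {"objects": (obj_images, obj_labels)}, sched2,
                 seed=seed + 10,
                 eval_data={"objects": (obj_test_images, obj_test_labels)})

    info = {
        "words": words,
        "canvas": canvas,
        "log": {"phase1": log1, "literate": log2, "illiterate": log3},
        "word_test_acc": float(log2["acc_words"].iloc[-1]),
        "object_test_acc": {
            "literate": float(log2["acc_objects"].iloc[-1]),
            "illiterate": float(log3["acc_objects"].iloc[-1]),
        },
    }
    return literate, illiterate, info


def probe_networks(literate: CORnetZ, illiterate: CORnetZ,
                   profile: ScaledProfile, seed: int, info: dict
                   ) -> EmergenceResult:
    """Localizer, dissimilarity and response-profile suite on a pair."""
    canvas = info["canvas"]
    nets = {"literate": literate, "illiterate": illiterate}

    # -- word-selective units (localizer contrast) -------------------------
    loc = stimgen.make_localizer_set(
        profile.localizer_words, profile.localizer_per_category,
        seed=seed + 3, words=info["words"], canvas=canvas)
    loc_images = np.stack([s.image for s in loc])
    loc_labels = np.array([s.label for s in loc])
    masks: dict[str, dict[str, np.ndarray]] = {}
    loc_stores: dict[str, ActivationStore] = {}
    for name, net in nets.items():
        store = record_activations(net, loc_images, PROBE_LAYERS)
        loc_stores[name] = store
        masks[name] = {
            layer: selectivity.localize_from_labelled(
                store, loc_labels, layer, k_sd=profile.k_sd)
            for layer in PROBE_LAYERS
        }
    n_selective = {name: {layer: int(m.sum()) for layer, m in by.items()}
                   for name, by in masks.items()}

    # -- bigram dissimilarity ---------------------------------------------
    bigrams = make_bigram_set(ALPHABET, profile.n_bigrams, seed=seed + 4,
                              canvas=canvas)
    mean_d: dict[str, dict[str, float]] = {}
    for name, net in nets.items():
        store = record_activations(net, bigrams, PROBE_LAYERS)
        mean_d[name] = {
            layer: rdm.mean_pairwise(store, layer, "bigrams").mean_d
            for layer in PROBE_LAYERS
        }

    # -- response profiles of literate word-selective units ----------------
    letter_stims = stimgen.make_single_letter_grid(ALPHABET, canvas=canvas)
    letter_store = record_activations(literate, np.stack(
        [s.image for s in letter_stims]), PROBE_LAYERS)
    probe_cache: dict[tuple[str, str], dict[str, ActivationStore]] = {}
    spaced_cache: dict[tuple[str, str], dict[str, ActivationStore]] = {}
    category_counts: dict[str, dict[str, int]] = {}
    late_total = late_ordinal = late_space = 0
    for layer in ("V4", "IT", "avgIT"):
        units = _selected_units(loc_stores["literate"], masks["literate"],
                                layer, profile.max_profile_units)
        counts: dict[str, int] = {}
        for unit in units:
            tuning = selectivity.letter_tuning(unit, letter_store, ALPHABET)
            pair = (tuning.best_letter, tuning.worst_letter)
            if pair[0] == pair[1]:  # flat tuning table, nothing to probe
                continue
            if pair not in probe_cache:
                design = stimgen.make_factorial_probe(*pair, canvas=canvas)
                probe_cache[pair] = {
                    "design": design,
                    "store": record_activations(
                        literate, np.stack([s.image for s in design.stimuli]),
                        PROBE_LAYERS),
                }
            entry = probe_cache[pair]
            rm = prof.classify_unit(unit, entry["store"], entry["design"],
                                    exclusion=profile.exclusion)
            counts[rm.category] = counts.get(rm.category, 0) + 1
            if layer in LATE_LAYERS and not rm.excluded:
                late_total += 1
                if rm.category == "ordinal":
                    late_ordinal += 1
                if pair not in spaced_cache:
                    sdesign = stimgen.make_spaced_probe(*pair, canvas=canvas)
                    spaced_cache[pair] = {
                        "design": sdesign,
                        "store": record_activations(
                            literate,
                            np.stack([s.image for s in sdesign.stimuli]),
                            PROBE_LAYERS),
                    }
                sentry = spaced_cache[pair]
                sraw = prof.build_response_matrix(unit, sentry["store"],
                                                  sentry["design"])
                sbin, sexcl = prof.binarize(sraw,
                                            exclusion=profile.exclusion)
                if prof.spaced_reclassify(rm.category, sbin,
                                          sexcl) == "space_bigram":
                    late_space += 1
        category_counts[layer] = counts

    return EmergenceResult(
        seed=seed, profile=profile,
        word_test_acc=info["word_test_acc"],
        object_test_acc=info["object_test_acc"],
        train_log=info["log"],
        n_selective=n_selective, mean_d=mean_d,
        category_counts=category_counts,
        ordinal_fraction_late=(late_ordinal / late_total
                               if late_total else 0.0),
        n_space_bigram_late=late_space,
    )


def _selected_units(store: ActivationStore, masks: dict[str, np.ndarray],
                    layer: str, max_units: int) -> list[UnitAddress]:
    mask = masks[layer]
    idx = np.flatnonzero(mask)[:max_units]
    addresses = store.unit_addresses(layer)
    return [addresses[i] for i in idx]


def run_scaled_experiment(seed: int,
                          profile: ScaledProfile | None = None
                          ) -> EmergenceResult:
    """Train one literate/illiterate pair and probe both."""
    profile = profile or ScaledProfile()
    literate, illiterate, info = train_pair(profile, seed)
    return probe_networks(literate, illiterate, profile, seed, info)
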