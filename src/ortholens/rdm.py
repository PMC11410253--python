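"""Correlation-distance representational dissimilarity analyses.

The dissimilarity between two stimuli at a layer is d = 1 - r, where r
is the Pearson correlation between the stimuli's vectorized activation
patterns (all units of the layer).  Literate-vs-illiterate comparisons
test, per layer, whether the mean pairwise dissimilarity over a stimulus
set (e.g. 49 bigrams -> 1176 pairs) differs between two networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .store import ActivationStore


@dataclass
class DissimilarityResult:
    layer: str
    stimulus_set: str
    pair_values: np.ndarray  # all C(n,2) distances, fixed pair order
    n_stimuli: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_values)

    @property
    def mean_d(self) -> float:
        return float(self.pair_values.mean())


def dissimilarity(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """d = 1 - Pearson r between two activation vectors (d in [0, 2])."""
    a = np.asarray(vec_a, dtype=np.float64).ravel()
    b = np.asarray(vec_b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must share a length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance activation vector")
    return 1.0 - float(np.corrcoef(a, b)[0, 1])


def mean_pairwise(store_or_array, layer: str | None = None,
                  stimulus_set: str = "") -> DissimilarityResult:
    """All C(n,2) pairwise dissimilarities at one layer.

    Stimuli with zero activation variance cannot enter a correlation and
    are dropped with a warning.  Accepts an ActivationStore plus a layer
    name, or directly an (n_stimuli, n_units) array.
    """
    if isinstance(store_or_array, ActivationStore):
        X = store_or_array.flat(layer)
    else:
        X = np.asarray(store_or_array, dtype=np.float64)
        X = X.reshape(X.shape[0], -1)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"dropping {int((sd == 0).sum())} zero-variance stimuli from "
            "the dissimilarity set", stacklevel=2)
        X = X[sd > 0]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 valid stimuli")
    r = np.corrcoef(X)
    iu = np.triu_indices(n, k=1)
    return DissimilarityResult(
        layer=layer or "", stimulus_set=stimulus_set,
        pair_values=1.0 - r[iu], n_stimuli=n,
    )


@dataclass
class NetworkComparison:
    layer: str
    mean_diff: float  # mean_d(a) - mean_d(b)
    t_stat: float
    p_value: float  # paired two-sided t test over matched pairs
    p_permutation: float  # sign-flip permutation alternative
    n_pairs: int


def compare_networks(result_a: DissimilarityResult,
                     result_b: DissimilarityResult,
                     n_permutations: int = 1000,
                     seed: int = 0) -> NetworkComparison:
    """Paired comparison of matched pair dissimilarities at one layer.

    Reports the paired two-sided t test alongside a seeded sign-flip
    permutation test on the pair differences.
    """
    if (result_a.n_pairs != result_b.n_pairs
            or result_a.layer != result_b.layer):
        raise ValueError("results must share the layer and stimulus pairs")
    d = result_a.pair_values - result_b.pair_values
    if np.allclose(d, 0):
        t, p = 0.0, 1.0
    elif np.ptp(d) < 1e-12:  # exactly uniform shift: degenerate t
        t, p = np.inf * np.sign(d[0]), 0.0
    else:
        t, p = stats.ttest_rel(result_a.pair_values, result_b.pair_values)
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    null = np.abs((signs * d).mean(axis=1))
    p_perm = float((np.sum(null >= obs) + 1) / (n_permutations + 1))
    return NetworkComparison(
        layer=result_a.layer, mean_diff=float(d.mean()),
        t_stat=float(t), p_value=float(p), p_permutation=p_perm,
        n_pairs=result_a.n_pairs,
    )


def compare_by_layer(stores_a: dict[str, DissimilarityResult],
                     stores_b: dict[str, DissimilarityResult],
                     **kwargs) -> pd.DataFrame:
    rows = []
    for layer in stores_a:
        c = compare_networks(stores_a[layer], stores_b[layer], **kwargs)
        rows.append({
            "layer": layer, "mean_diff": c.mean_diff, "t": c.t_stat,
            "p": c.p_value, "p_perm": c.p_permutation, "n_pairs": c.n_pairs,
        })
    return pd.DataFrame(rows)
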