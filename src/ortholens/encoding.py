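"""Letter-by-position encoding models.

A unit's responses Y over a word set are modelled as Y = Xb where X is a
binary words x (letters x slots) design matrix under one of three
position schemes:

* ``left_aligned``  — letter i of a word occupies slot i (from word start);
* ``word_centered`` — the word is shifted to the centre of the 8-slot frame;
* ``edge_aligned``  — initial letters index from the word's start, final
  letters from its end ("WORD" -> W1 O2 R7 D8).

b is estimated with L1-regularised linear regression, the penalty chosen
by internal cross-validation (LassoCV); model fit is the Pearson
correlation between held-out predictions and observed responses,
averaged over outer folds.  Since the three schemes have identical
parameter counts, their cross-validated correlations are directly
comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .lexicon import ALPHABET

SCHEMES = ("left_aligned", "word_centered", "edge_aligned")


@dataclass
class DesignMatrix:
    scheme: str
    words: tuple[str, ...]
    X: np.ndarray  # (n_words, n_letters * n_slots), binary
    alphabet: str = ALPHABET
    n_slots: int = 8

    def feature_index(self, letter: str, slot: int) -> int:
        """Column of (letter, slot); slot is 0-based."""
        return len(self.alphabet) * slot + self.alphabet.index(letter.lower())

    def coefficients_table(self, b: np.ndarray) -> np.ndarray:
        """Reshape a coefficient vector to (n_letters, n_slots)."""
        return b.reshape(self.n_slots, len(self.alphabet)).T


def scheme_slots(word: str, scheme: str, n_slots: int = 8) -> list[int]:
    """0-based slot of each letter of ``word`` under a position scheme."""
    L = len(word)
    if L > n_slots:
        raise ValueError(f"word {word!r} longer than the {n_slots}-slot frame")
    if scheme == "left_aligned":
        return list(range(L))
    if scheme == "word_centered":
        off = (n_slots - L) // 2
        return [off + i for i in range(L)]
    if scheme == "edge_aligned":
        n_front = math.ceil(L / 2)
        slots = list(range(n_front))
        n_back = L - n_front
        slots += [n_slots - n_back + i for i in range(n_back)]
        return slots
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def build_design_matrix(words, scheme: str, alphabet: str = ALPHABET,
                        n_slots: int = 8) -> DesignMatrix:
    """Binary word x (letter, slot) design matrix under one scheme.

    Words are case-folded; each row has exactly word-length ones.  For
    8-letter words all three schemes coincide (every slot is occupied).
    """
    words = tuple(w.lower() for w in words)
    n_feat = len(alphabet) * n_slots
    X = np.zeros((len(words), n_feat), dtype=np.float64)
    for r, word in enumerate(words):
        if not word.isalpha():
            raise ValueError(f"word {word!r} is not alphabetic")
        for letter, slot in zip(word, scheme_slots(word, scheme, n_slots)):
            X[r, len(alphabet) * slot + alphabet.index(letter)] = 1.0
    return DesignMatrix(scheme=scheme, words=words, X=X,
                        alphabet=alphabet, n_slots=n_slots)


@dataclass
class EncodingFit:
    scheme: str
    b: np.ndarray  # full-data coefficients, (n_features,)
    intercept: float
    cv_r: float  # Pearson r between out-of-fold predictions and Y
    alpha: float  # selected L1 penalty (full-data fit)
    degenerate: bool = False
    unit: object = None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_encoding(Y: np.ndarray, X, cv_folds: int = 5,
                 seed: int = 0, unit=None) -> EncodingFit:
    """Cross-validated lasso encoding fit for one unit.

    The outer K-fold (shuffled, seeded) supplies held-out predictions;
    cv_r is the mean over folds of the Pearson correlation between each
    fold's held-out predictions and responses.  (Pooling predictions
    across folds before correlating carries a negative finite-sample
    bias from anti-correlated fold means, which would shift the
    permutation null away from zero; per-fold averaging removes it.)
    The reported coefficients come from a full-data LassoCV fit.  A
    constant response vector cannot be fit and is returned with
    cv_r = 0 and the degenerate flag set.
    """
    dm = X if isinstance(X, DesignMatrix) else None
    Xa = X.X if dm is not None else np.asarray(X)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != Xa.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows, X has {Xa.shape[0]}")
    scheme = dm.scheme if dm is not None else "custom"
    if np.ptp(Y) == 0:
        return EncodingFit(scheme=scheme, b=np.zeros(Xa.shape[1]),
                           intercept=float(Y[0]) if len(Y) else 0.0,
                           cv_r=0.0, alpha=0.0, degenerate=True, unit=unit)

    def make_lasso():
        # 30 alphas along the default log grid; plenty for a binary X
        return LassoCV(cv=5, alphas=30, max_iter=5000, tol=1e-4,
                       random_state=seed)

    fold_r = []
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in kf.split(Xa):
            if np.ptp(Y[te]) == 0:
                # constant held-out responses carry no correlation signal
                continue
            model = make_lasso().fit(Xa[tr], Y[tr])
            fold_r.append(_pearson(model.predict(Xa[te]), Y[te]))
        full = make_lasso().fit(Xa, Y)
    return EncodingFit(
        scheme=scheme, b=full.coef_.copy(), intercept=float(full.intercept_),
        cv_r=float(np.mean(fold_r)) if fold_r else 0.0,
        alpha=float(full.alpha_), degenerate=not fold_r, unit=unit,
    )


def compare_schemes(unit_responses: np.ndarray, words,
                    schemes=SCHEMES, cv_folds: int = 5, seed: int = 0,
                    tie_tol: float = 0.02,
                    alphabet: str = ALPHABET, n_slots: int = 8
                    ) -> pd.DataFrame:
    """Fit every scheme to every unit with the identical protocol.

    ``unit_responses`` is (n_words,) for one unit or (n_words, n_units).
    Returns one row per unit with per-scheme cv_r, the winning scheme,
    and a tie flag set when the top two schemes are within ``tie_tol``.
    """
    Y = np.asarray(unit_responses, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    designs = {s: build_design_matrix(words, s, alphabet, n_slots)
               for s in schemes}
    rows = []
    for u in range(Y.shape[1]):
        r = {}
        for s in schemes:
            r[s] = fit_encoding(Y[:, u], designs[s], cv_folds, seed).cv_r
        ranked = sorted(r, key=r.get, reverse=True)
        rows.append({
            "unit": u, **{f"cv_r_{s}": r[s] for s in schemes},
            "winner": ranked[0],
            "tie": len(ranked) > 1 and r[ranked[0]] - r[ranked[1]] < tie_tol,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# position tuning


@dataclass
class PositionTuningCurve:
    group: int  # preferred slot, 0-based
    curve: np.ndarray  # length n_slots, max-normalised then averaged
    n_units: int


def position_tuning(fits: list[EncodingFit], alphabet: str = ALPHABET,
                    n_slots: int = 8) -> list[PositionTuningCurve]:
    """Group units by preferred slot and average normalised profiles.

    Per unit: reshape coefficients to (letters, slots), average over
    letters, normalise the length-``n_slots`` profile by its own maximum,
    group by argmax slot, then average within each group.
    """
    schemes = {f.scheme for f in fits}
    if len(schemes) > 1:
        raise ValueError(f"fits mix schemes: {sorted(schemes)}")
    profiles: dict[int, list[np.ndarray]] = {}
    for f in fits:
        table = f.b.reshape(n_slots, len(alphabet)).T
        prof = table.mean(axis=0)
        peak = np.abs(prof).max()
        if peak == 0:
            warnings.warn("unit with all-zero coefficients dropped from "
                          "position tuning", stacklevel=2)
            continue
        prof = prof / prof.max() if prof.max() > 0 else prof / peak
        profiles.setdefault(int(np.argmax(prof)), []).append(prof)
    return [
        PositionTuningCurve(group=g, curve=np.mean(ps, axis=0),
                            n_units=len(ps))
        for g, ps in sorted(profiles.items())
    ]


def peak_to_mean_sharpness(curve: np.ndarray) -> float:
    """Peak over mean of a tuning curve; larger = sharper tuning."""
    m = float(np.mean(curve))
    return float(np.max(curve) / m) if m != 0 else np.inf


def permutation_cv_r(Y: np.ndarray, X, n_shuffles: int = 100,
                     seed: int = 0, cv_folds: int = 5) -> np.ndarray:
    """Null distribution of cv_r under response permutation."""
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, dtype=np.float64)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = fit_encoding(rng.permutation(Y), X, cv_folds,
                              seed=int(rng.integers(2 ** 31))).cv_r
    return out
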