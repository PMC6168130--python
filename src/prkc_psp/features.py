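"""Amino-acid location feature encoding.

Each 31-mer window is mapped to a 62-dimensional vector: components 1..31 are
the position-specific occurrence frequencies of the window's own residues
among the *positive* training peptides, components 32..62 the same frequencies
among the *negative* training peptides.  A window that "looks like" known
phosphosites therefore scores high in its first half and low in its second,
and vice versa — the SVM separates the two regimes.

Frequencies are plain occurrence counts divided by the class size; by default
no pseudocounts are added, so a residue never seen at a position in a class
contributes exactly 0 (an additive-smoothing hook exists but defaults off).
The padding symbol X is counted like any other residue, which makes terminal
proximity an implicit feature of the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dataio import ALPHABET, WINDOW_LENGTH, PeptideWindow

N_SYMBOLS = len(ALPHABET)  # 21
N_FEATURES = 2 * WINDOW_LENGTH  # 62

_SYMBOL_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class UnfittedModelError(RuntimeError):
    """Raised when encoding/scaling is attempted before fitting."""


def window_indices(windows: Sequence[PeptideWindow]) -> np.ndarray:
    """Integer-encode windows as an (n, 31) matrix of alphabet indices."""
    arr = np.empty((len(windows), WINDOW_LENGTH), dtype=np.intp)
    for i, w in enumerate(windows):
        for j, c in enumerate(w.peptide):
            arr[i, j] = _SYMBOL_INDEX[c]
    return arr


@dataclass
class PositionFrequencyModel:
    """Per-position residue frequencies of positive and negative training windows.

    ``f_pos`` and ``f_neg`` are (31, 21) matrices over the alphabet
    ``ACDEFGHIKLMNPQRSTVWYX``; each row sums to 1 when the class is nonempty
    and no smoothing is applied.
    """

    f_pos: np.ndarray
    f_neg: np.ndarray
    n_pos_train: int
    n_neg_train: int
    pseudocount: float = 0.0

    def frequency(self, klass: str, position: int, residue: str) -> float:
        """Look up a frequency; ``position`` is 1-based (1..31)."""
        mat = self.f_pos if klass == "positive" else self.f_neg
        return float(mat[position - 1, _SYMBOL_INDEX[residue]])


def _class_frequencies(idx: np.ndarray, pseudocount: float) -> np.ndarray:
    counts = np.zeros((WINDOW_LENGTH, N_SYMBOLS))
    for j in range(WINDOW_LENGTH):
        counts[j] = np.bincount(idx[:, j], minlength=N_SYMBOLS)
    counts += pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def fit_frequency_model(
    training_windows: Iterable[PeptideWindow], pseudocount: float = 0.0
) -> PositionFrequencyModel:
    """Count residue occurrences per position, separately per class.

    Built strictly from the windows handed in — inside cross-validation that
    is the training fold only, so held-out peptides never leak into the
    frequency matrices.
    """
    windows = list(training_windows)
    pos = [w for w in windows if w.label == "positive"]
    neg = [w for w in windows if w.label == "negative"]
    if not pos or not neg:
        missing = "positive" if not pos else "negative"
        raise ValueError(f"cannot fit frequency model: no {missing} windows")
    return PositionFrequencyModel(
        f_pos=_class_frequencies(window_indices(pos), pseudocount),
        f_neg=_class_frequencies(window_indices(neg), pseudocount),
        n_pos_train=len(pos),
        n_neg_train=len(neg),
        pseudocount=pseudocount,
    )


def encode(window: PeptideWindow, model: PositionFrequencyModel) -> np.ndarray:
    """Encode one window as its 62-vector of location features."""
    return encode_windows([window], model)[0]


def encode_windows(
    windows: Sequence[PeptideWindow], model: PositionFrequencyModel
) -> np.ndarray:
    """Vectorized encoding of many windows; rows are 62-dimensional."""
    if model is None:
        raise UnfittedModelError("frequency model not fitted")
    idx = window_indices(windows)
    cols = np.arange(WINDOW_LENGTH)
    out = np.empty((len(windows), N_FEATURES))
    out[:, :WINDOW_LENGTH] = model.f_pos[cols, idx]
    out[:, WINDOW_LENGTH:] = model.f_neg[cols, idx]
    return out


@dataclass
class Scaler:
    """Min-max rescaling to [0, 1], fitted on training vectors.

    Raw location features are already frequencies in [0, 1], so this is close
    to the identity; it pins the feature ranges so SVM kernel widths mean the
    same thing across folds.  Constant features map to 0 and query values
    outside the training range are clipped.
    """

    mins: np.ndarray
    maxs: np.ndarray
    feature_range: tuple[float, float] = (0.0, 1.0)


def fit_scaler(vectors: np.ndarray) -> Scaler:
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 1:
        raise ValueError("need a 2-D array with at least one training vector")
    return Scaler(mins=vectors.min(axis=0), maxs=vectors.max(axis=0))


def apply_scaler(vectors: np.ndarray, scaler: Scaler) -> np.ndarray:
    """Scale vectors (1-D or 2-D) into [0, 1] per feature, clipping overshoot."""
    x = np.asarray(vectors, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != scaler.mins.shape[0]:
        raise ValueError(
            f"dimension mismatch: {x.shape[1]} features vs scaler {scaler.mins.shape[0]}"
        )
    span = scaler.maxs - scaler.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (x - scaler.mins) / safe
    scaled = np.where(span > 0, scaled, 0.0)
    lo, hi = (0.0, 1.0)
    scaled = np.clip(scaled, lo, hi)
    return scaled[0] if single else scaled


def export_frequency_tsv(model: PositionFrequencyModel, path: str | Path) -> None:
    """Dump both frequency matrices as a human-readable TSV for inspection."""
    with open(path, "w") as fh:
        fh.write("class\tposition\toffset\t" + "\t".join(ALPHABET) + "\n")
        for name, mat in (("positive", model.f_pos), ("negative", model.f_neg)):
            for j in range(WINDOW_LENGTH):
                offset = j + 1 - (WINDOW_LENGTH // 2 + 1)
                vals = "\t".join(f"{v:.6f}" for v in mat[j])
                fh.write(f"{name}\t{j + 1}\t{offset:+d}\t{vals}\n")
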