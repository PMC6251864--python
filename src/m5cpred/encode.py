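"""Numeric feature encodings for candidate-C sequence windows.

Two schemes are implemented, both producing ``(2w+1) * 4`` features in
position-major order (the four components of position 1, then position 2,
and so on, 5'→3'):

``one_hot``
    A→(1,0,0,0), G→(0,1,0,0), C→(0,0,1,0), T→(0,0,0,1). ``N`` encodes as
    the all-zero vector, marking an absent/unknown base.

``feng``
    Three fixed physicochemical indicator bits per base — ring number,
    chemical functionality, hydrogen-bond count — followed by the
    accumulated occurrence frequency of that base up to and including its
    position: A→(1,1,1,FreqA), G→(1,0,0,FreqG), C→(0,1,0,FreqC),
    T→(0,0,1,FreqT). The frequency at position i is the count of that
    nucleotide among window positions 1..i divided by the number of non-N
    bases among positions 1..i. ``N`` encodes as all zeros and is excluded
    from later denominators, so frequencies stay interpretable as
    fractions of observed bases.

The accumulated frequency is computed over the extracted window only, not
the full transcript: a prediction server only ever sees windows, and local
encoding keeps features cacheable. ``feng_encode(..., full_sequence=...)``
exposes the whole-sequence alternative for anyone who wants the frequency
normalised over a longer context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EncodingError, ShapeMismatchError
from .seqio import SequenceWindow

SCHEMES = ("one_hot", "feng")

_BASE_ORDER = "AGCT"  # column order of the 4 one-hot components
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}

_ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "G": (0.0, 1.0, 0.0, 0.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0, 0.0),
}

# ring number, chemical functionality, hydrogen-bond count
_FENG_TRIPLE = {
    "A": (1.0, 1.0, 1.0),
    "G": (1.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class FeatureVector:
    """One encoded window: 4 components per position, position-major.

    For a true candidate window of flank size w, ``n_positions = 2w+1`` and
    the vector length is ``(2w+1)*4``.
    """

    values: tuple[float, ...]
    scheme: str
    n_positions: int

    def __post_init__(self) -> None:
        if len(self.values) != self.n_positions * 4:
            raise ValueError(
                f"feature length {len(self.values)} != 4*{self.n_positions}"
            )

    @property
    def w(self) -> int:
        if self.n_positions % 2 == 0:
            raise ValueError("even-width vector has no centred flank size")
        return (self.n_positions - 1) // 2


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with an optional parallel 0/1 label vector."""

    values: np.ndarray  # shape (n_windows, (2w+1)*4)
    scheme: str
    w: int
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != (2 * self.w + 1) * 4:
            raise ShapeMismatchError(
                f"feature matrix width {self.values.shape} does not match "
                f"(2w+1)*4 = {(2 * self.w + 1) * 4}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ShapeMismatchError("labels not parallel to rows")

    def column_names(self) -> list[str]:
        names = []
        for offset in range(-self.w, self.w + 1):
            tag = f"p{offset:+d}" if offset else "p0"
            if self.scheme == "one_hot":
                parts = ("A", "G", "C", "T")
            else:
                parts = ("ring", "func", "hbond", "freq")
            names.extend(f"{tag}.{p}" for p in parts)
        return names

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.column_names())
        if self.labels is not None:
            frame.insert(0, "label", self.labels)
        return frame

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_bases(bases: str) -> None:
    for base in bases:
        if base not in _ONE_HOT:
            raise EncodingError(f"cannot encode base {base!r}")


def _bases_of(window: "SequenceWindow | str") -> str:
    return window if isinstance(window, str) else window.bases


def one_hot_encode(window: SequenceWindow | str) -> FeatureVector:
    """Encode one window (or a bare base string) with the 4-bit identity
    scheme."""
    bases = _bases_of(window)
    _check_bases(bases)
    values: list[float] = []
    for base in bases:
        values.extend(_ONE_HOT[base])
    return FeatureVector(values=tuple(values), scheme="one_hot",
                         n_positions=len(bases))


def feng_encode(window: SequenceWindow | str,
                full_sequence: str | None = None) -> FeatureVector:
    """Encode one window with physicochemical bits + accumulated frequency.

    With ``full_sequence`` (the whole transcript the window came from) the
    accumulated frequency of the base at window position i is computed over
    the transcript prefix ending at that base's 1-based transcript
    coordinate ``center_index - w + i`` — the whole-input convention some
    encoders use — instead of over the window alone. ``full_sequence``
    requires a true :class:`SequenceWindow` (it needs the coordinate).
    """
    bases = _bases_of(window)
    _check_bases(bases)
    values: list[float] = []
    if full_sequence is None:
        counts = {b: 0 for b in _BASE_ORDER}
        observed = 0
        for base in bases:
            if base == "N":
                values.extend((0.0, 0.0, 0.0, 0.0))
                continue
            counts[base] += 1
            observed += 1
            values.extend((*_FENG_TRIPLE[base], counts[base] / observed))
    else:
        if isinstance(window, str):
            raise EncodingError(
                "full_sequence frequency needs a SequenceWindow with a "
                "transcript coordinate"
            )
        start = window.center_index - window.w  # 1-based coord of window pos 0
        for i, base in enumerate(bases):
            if base == "N":
                values.extend((0.0, 0.0, 0.0, 0.0))
                continue
            prefix = full_sequence[:start + i]
            observed = sum(1 for b in prefix if b != "N")
            freq = prefix.count(base) / observed if observed else 0.0
            values.extend((*_FENG_TRIPLE[base], freq))
    return FeatureVector(values=tuple(values), scheme="feng",
                         n_positions=len(bases))


def decode_one_hot(vector: FeatureVector) -> str:
    """Invert :func:`one_hot_encode` (injective on {A,C,G,T,N} windows)."""
    if vector.scheme != "one_hot":
        raise EncodingError(f"cannot decode scheme {vector.scheme!r}")
    arr = np.asarray(vector.values).reshape(-1, 4)
    bases = []
    for row in arr:
        hot = np.flatnonzero(row == 1.0)
        if hot.size == 0:
            bases.append("N")
        elif hot.size == 1:
            bases.append(_BASE_ORDER[hot[0]])
        else:
            raise EncodingError("row with more than one hot bit")
    return "".join(bases)


def encode_batch(windows: Sequence[SequenceWindow], scheme: str = "one_hot",
                 labels: Iterable[int] | None = None,
                 w: int | None = None) -> FeatureMatrix:
    """Vectorised encoding of many windows sharing one width.

    Row order preserves input order; the result equals mapping the
    single-window encoder over the batch. ``w`` only needs to be given for
    an empty batch, where the width is otherwise unknowable; for a
    non-empty batch it must agree with the windows when provided.
    """
    if scheme not in SCHEMES:
        raise EncodingError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    windows = list(windows)
    label_arr = None if labels is None else np.asarray(list(labels), dtype=int)
    if not windows:
        if w is None:
            raise ShapeMismatchError("empty batch needs an explicit w")
        return empty_matrix(w, scheme)
    if w is not None and windows[0].w != w:
        raise ShapeMismatchError(f"declared w={w} but windows have w={windows[0].w}")
    w = windows[0].w
    for win in windows:
        if win.w != w:
            raise ShapeMismatchError(
                f"mixed window widths in batch: {win.w} vs {w}"
            )
    length = 2 * w + 1
    codes = np.empty((len(windows), length), dtype=np.int8)
    lookup = np.full(128, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lookup[ord(base)] = idx
    lookup[ord("N")] = 4
    for row, win in enumerate(windows):
        raw = np.frombuffer(win.bases.encode("ascii"), dtype=np.uint8)
        codes[row] = lookup[raw]
    if (codes < 0).any():
        bad = windows[int(np.argwhere(codes < 0)[0][0])]
        raise EncodingError(f"cannot encode window {bad.bases!r}")

    eye5 = np.vstack([np.eye(4), np.zeros(4)])  # N -> all-zero row
    onehot = eye5[codes]  # (n, L, 4)
    if scheme == "one_hot":
        values = onehot.reshape(len(windows), length * 4)
        return FeatureMatrix(values=values, scheme="one_hot", w=w,
                             labels=label_arr)

    # feng: physicochemical triples + running per-base frequency
    triples = np.vstack([
        [_FENG_TRIPLE[b] for b in _BASE_ORDER],
        [(0.0, 0.0, 0.0)],
    ])[codes]  # (n, L, 3)
    cum_counts = np.cumsum(onehot, axis=1)  # count of each base among 1..i
    observed = np.cumsum(codes != 4, axis=1)  # non-N bases among 1..i
    own = np.take_along_axis(
        cum_counts, np.minimum(codes, 3)[..., None].astype(int), axis=2
    )[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(observed > 0, own / np.maximum(observed, 1), 0.0)
    freq[codes == 4] = 0.0
    values = np.concatenate([triples, freq[..., None]], axis=2)
    return FeatureMatrix(values=values.reshape(len(windows), length * 4),
                         scheme="feng", w=w, labels=label_arr)


def empty_matrix(w: int, scheme: str = "one_hot") -> FeatureMatrix:
    """An 0-row matrix with the declared ``(2w+1)*4`` width."""
    if scheme not in SCHEMES:
        raise EncodingError(f"unknown scheme {scheme!r}")
    return FeatureMatrix(values=np.empty((0, (2 * w + 1) * 4)), scheme=scheme, w=w)
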