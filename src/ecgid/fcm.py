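"""Finite-context-model counting and coding.

An order-``k`` finite-context model (FCM) estimates the probability of the
next symbol from the ``k`` immediately preceding symbols via smoothed counts:

    P(s | c) = (v(s|c) + alpha) / (sum_a v(a|c) + alpha * |A|)

where ``v(s|c)`` is the number of times symbol ``s`` followed context ``c``
in the training sequence and ``alpha > 0`` interpolates between the
maximum-likelihood estimate and the uniform distribution.  The code length
of a sequence ``x`` under a model is ``-sum_i log2 P(x_i | context_i)``;
contexts for the first ``k`` positions wrap around circularly, both during
training and during coding, so every position contributes exactly one count
and one code term.

The *relative compression* C(x||y) is the code length of ``x`` under a model
built exclusively from ``y`` and kept static while coding (no adaptive
updates from ``x``), which is the similarity primitive the identification
stage builds on.

Counts are stored sparsely as sorted fixed-width byte keys (context plus
following symbol), which keeps order-20 models over 20-symbol alphabets
tractable: the number of stored contexts is bounded by the training length,
never by ``|A|^k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, StateError
from .signal_prep import SymbolSequence

__all__ = [
    "ContextModel",
    "CodeLength",
    "SequenceKeys",
    "ALPHA_GRID",
    "train",
    "prob",
    "code_length",
    "relative_compression",
    "resolve_alpha",
]

AlphaSpec = Union[float, str]

#: Candidate grid for the 'auto' smoothing rule, descending so that ties in
#: self-code length resolve toward the larger (more uniform) alpha.
ALPHA_GRID: tuple[float, ...] = (1.0, 0.5, 0.25, 0.1, 0.05, 0.02, 0.01)


def _window_keys(codes: np.ndarray, k: int, include_symbol: bool) -> np.ndarray:
    """Byte keys of the circular context (optionally + symbol) at each position.

    Position ``i`` yields the ``k`` symbols preceding it with wrap-around,
    followed by symbol ``i`` itself when ``include_symbol``.  Codes are
    shifted by +1 so no key byte is NUL (numpy 'S' dtype strips trailing
    NULs, which would corrupt fixed-width comparisons).
    """
    n = codes.size
    offsets = np.arange(-k, 1 if include_symbol else 0, dtype=np.int64)
    idx = (np.arange(n, dtype=np.int64)[:, None] + offsets[None, :]) % n
    windows = (codes + 1).astype(np.uint8)[idx]
    width = offsets.size
    return np.ascontiguousarray(windows).view(f"S{width}").ravel()


def _lookup(sorted_keys: np.ndarray, values: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Vectorized exact-match lookup in a sorted key array; 0 where absent."""
    if sorted_keys.size == 0:
        return np.zeros(queries.size, dtype=np.int64)
    pos = np.searchsorted(sorted_keys, queries)
    pos_c = np.minimum(pos, sorted_keys.size - 1)
    found = sorted_keys[pos_c] == queries
    return np.where(found, values[pos_c], 0)


@dataclass(frozen=True)
class ContextModel:
    """An order-``k`` conditional count table with smoothing ``alpha``.

    ``keys``/``key_counts`` hold the (context, symbol) pair counts,
    ``ctx_keys``/``ctx_totals`` the per-context totals; both sorted for
    binary-search lookup.  ``alpha`` may still be the token ``'auto'`` if it
    has not been resolved yet, in which case probability queries refuse.
    """

    k: int
    alphabet: tuple[str, ...]
    alpha: AlphaSpec
    keys: np.ndarray = field(repr=False)
    key_counts: np.ndarray = field(repr=False)
    ctx_keys: np.ndarray = field(repr=False)
    ctx_totals: np.ndarray = field(repr=False)
    n_train: int = 0
    alpha_spec: AlphaSpec = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidParameterError("context order k must be >= 1")
        if self.alpha_spec is None:
            object.__setattr__(self, "alpha_spec", self.alpha)

    @classmethod
    def empty(cls, k: int, alphabet: tuple[str, ...], alpha: AlphaSpec = 1.0) -> "ContextModel":
        """A model with no counts: every probability is uniform 1/|A|."""
        return cls(
            k=k,
            alphabet=tuple(alphabet),
            alpha=alpha,
            keys=np.empty(0, dtype=f"S{k + 1}"),
            key_counts=np.empty(0, dtype=np.int64),
            ctx_keys=np.empty(0, dtype=f"S{k}"),
            ctx_totals=np.empty(0, dtype=np.int64),
            n_train=0,
        )

    @property
    def total_count(self) -> int:
        return int(self.key_counts.sum())

    def _require_alpha(self) -> float:
        if isinstance(self.alpha, str):
            raise StateError("alpha is 'auto' and has not been resolved to a number")
        if not self.alpha > 0:
            raise InvalidParameterError("alpha must be positive")
        return float(self.alpha)

    # -- serialization (lossless round-trip) --------------------------------

    def to_dict(self) -> dict:
        lut = {i: c for i, c in enumerate(self.alphabet)}
        entries = []
        for key, count in zip(self.keys, self.key_counts):
            raw = key.ljust(self.k + 1, b"\x00")  # 'S' dtype strips trailing NULs
            codes = np.frombuffer(raw, dtype=np.uint8) - 1
            text = "".join(lut[c] for c in codes)
            entries.append([text[: self.k], text[self.k], int(count)])
        return {
            "schema_version": 1,
            "k": self.k,
            "alphabet": list(self.alphabet),
            "alpha": self.alpha,
            "alpha_spec": self.alpha_spec,
            "n_train": self.n_train,
            "counts": entries,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ContextModel":
        k = int(data["k"])
        alphabet = tuple(data["alphabet"])
        lut = {c: i for i, c in enumerate(alphabet)}
        n = len(data["counts"])
        keys = np.empty(n, dtype=f"S{k + 1}")
        counts = np.empty(n, dtype=np.int64)
        for i, (ctx, sym, count) in enumerate(data["counts"]):
            codes = np.array([lut[c] + 1 for c in ctx + sym], dtype=np.uint8)
            keys[i] = codes.tobytes()
            counts[i] = count
        order = np.argsort(keys)
        keys, counts = keys[order], counts[order]
        ctx_part = np.array([key.ljust(k + 1, b"\x00")[:k] for key in keys], dtype=f"S{k}")
        ctx_keys, inverse = np.unique(ctx_part, return_inverse=True)
        ctx_totals = np.zeros(ctx_keys.size, dtype=np.int64)
        np.add.at(ctx_totals, inverse, counts)
        return cls(
            k=k,
            alphabet=alphabet,
            alpha=data["alpha"],
            keys=keys,
            key_counts=counts,
            ctx_keys=ctx_keys,
            ctx_totals=ctx_totals,
            n_train=int(data["n_train"]),
            alpha_spec=data.get("alpha_spec", data["alpha"]),
        )


@dataclass(frozen=True)
class CodeLength:
    """Total bits needed to code a sequence, plus its length in symbols."""

    bits: float
    n_symbols: int

    def __post_init__(self) -> None:
        if self.bits < 0 or not math.isfinite(self.bits):
            raise InvalidInputError("code length must be finite and non-negative")

    @property
    def bits_per_symbol(self) -> float:
        return self.bits / self.n_symbols


def train(
    seq: SymbolSequence,
    k: int,
    alpha: AlphaSpec = "auto",
    resolve_auto: bool = True,
) -> ContextModel:
    """Accumulate circular (context, symbol) counts over ``seq``.

    Each of the ``n`` positions contributes one count, with the context of
    the first ``k`` positions wrapping to the end of the sequence, so the
    total stored count mass equals ``n``.  With ``alpha='auto'`` the
    smoothing parameter is resolved by self-compression grid search unless
    ``resolve_auto`` is disabled.
    """
    if k < 1:
        raise InvalidParameterError("context order k must be >= 1")
    if len(seq) < 1:
        raise InvalidInputError("training sequence must be non-empty")
    full = _window_keys(seq.codes, k, include_symbol=True)
    keys, key_counts = np.unique(full, return_counts=True)
    ctx = _window_keys(seq.codes, k, include_symbol=False)
    ctx_keys, ctx_totals = np.unique(ctx, return_counts=True)
    model = ContextModel(
        k=k,
        alphabet=seq.alphabet,
        alpha=alpha,
        keys=keys,
        key_counts=key_counts.astype(np.int64),
        ctx_keys=ctx_keys,
        ctx_totals=ctx_totals.astype(np.int64),
        n_train=len(seq),
    )
    if isinstance(alpha, str):
        if alpha != "auto":
            raise InvalidParameterError(f"alpha must be positive or 'auto', got {alpha!r}")
        if resolve_auto:
            resolved = _resolve_auto(model, seq)
            model = replace(model, alpha=resolved, alpha_spec="auto")
    elif not alpha > 0:
        raise InvalidParameterError("alpha must be positive")
    return model


@dataclass(frozen=True)
class SequenceKeys:
    """Precomputed circular window keys of one sequence at one order.

    Scoring the same test segment against many reference models reuses
    these instead of rebuilding the windows per model.
    """

    k: int
    n: int
    full: np.ndarray = field(repr=False)
    ctx: np.ndarray = field(repr=False)

    @classmethod
    def of(cls, x: SymbolSequence, k: int) -> "SequenceKeys":
        return cls(
            k=k,
            n=len(x),
            full=_window_keys(x.codes, k, include_symbol=True),
            ctx=_window_keys(x.codes, k, include_symbol=False),
        )


def _probabilities(model: ContextModel, keys: SequenceKeys, alpha: float) -> np.ndarray:
    """Per-position P(x_i | circular context of x at i) under the static model."""
    v = _lookup(model.keys, model.key_counts, keys.full)
    t = _lookup(model.ctx_keys, model.ctx_totals, keys.ctx)
    a_size = len(model.alphabet)
    # Unseen context: (0 + alpha) / (0 + alpha|A|) is exactly uniform.
    return np.where(t == 0, 1.0 / a_size, (v + alpha) / (t + alpha * a_size))


def prob(model: ContextModel, context: str, s: str) -> float:
    """Smoothed probability of symbol ``s`` after ``context`` (length ``k``)."""
    alpha = model._require_alpha()
    if len(context) != model.k:
        raise InvalidInputError(f"context must have length k={model.k}")
    lut = {c: i for i, c in enumerate(model.alphabet)}
    try:
        codes = np.array([lut[c] + 1 for c in context + s], dtype=np.uint8)
    except KeyError as exc:
        raise InvalidInputError(f"symbol {exc.args[0]!r} outside alphabet") from exc
    full = codes.tobytes()
    ctx = codes[:-1].tobytes()
    v = int(_lookup(model.keys, model.key_counts, np.array([full], dtype=f"S{model.k + 1}"))[0])
    t = int(_lookup(model.ctx_keys, model.ctx_totals, np.array([ctx], dtype=f"S{model.k}"))[0])
    a_size = len(model.alphabet)
    if t == 0:
        return 1.0 / a_size
    return (v + alpha) / (t + alpha * a_size)


def code_length(
    x: SymbolSequence,
    model: ContextModel,
    alpha: float | None = None,
    keys: SequenceKeys | None = None,
) -> CodeLength:
    """Total bits to code ``x`` under the static model (counts frozen).

    ``bits = -sum_i log2 P(x_i | context_i)`` with circular contexts taken
    within ``x`` itself.  An explicit ``alpha`` overrides the model's;
    precomputed ``keys`` (see :class:`SequenceKeys`) skip the window build
    when scoring one segment against many models.
    """
    if len(x) < 1:
        raise InvalidInputError("cannot code an empty sequence")
    if x.alphabet != model.alphabet:
        raise InvalidInputError("sequence and model alphabets differ")
    if alpha is None:
        alpha = model._require_alpha()
    if keys is None:
        keys = SequenceKeys.of(x, model.k)
    elif keys.k != model.k or keys.n != len(x):
        raise InvalidInputError("precomputed keys do not match sequence and model order")
    p = _probabilities(model, keys, float(alpha))
    bits = float(-np.log2(p).sum())
    return CodeLength(bits=max(bits, 0.0), n_symbols=len(x))


def relative_compression(
    x: SymbolSequence, y: SymbolSequence, k: int, alpha: AlphaSpec = "auto"
) -> CodeLength:
    """C(x||y): bits to code ``x`` under a model built exclusively from ``y``."""
    if x.alphabet != y.alphabet:
        raise InvalidInputError("x and y must share an alphabet")
    model = train(y, k, alpha)
    return code_length(x, model)


def _resolve_auto(model: ContextModel, y: SymbolSequence) -> float:
    """Grid-search alpha minimizing the self-code length of ``y``.

    The per-position counts are independent of alpha, so they are gathered
    once and the seven candidate bit totals evaluated in closed form.  Ties
    resolve toward the larger alpha (the grid is descending).
    """
    keys = SequenceKeys.of(y, model.k)
    v = _lookup(model.keys, model.key_counts, keys.full)
    t = _lookup(model.ctx_keys, model.ctx_totals, keys.ctx)
    a_size = len(model.alphabet)
    best_alpha, best_bits = None, np.inf
    for alpha in ALPHA_GRID:
        bits = float(-np.log2((v + alpha) / (t + alpha * a_size)).sum())
        if bits < best_bits:
            best_alpha, best_bits = alpha, bits
    return best_alpha


def resolve_alpha(spec: AlphaSpec, y: SymbolSequence | None = None, k: int | None = None) -> float:
    """Resolve an alpha specification to a number.

    Numeric specs pass through (after a positivity check).  ``'auto'``
    requires the training sequence ``y`` and order ``k`` and returns the
    grid candidate minimizing the self-code length of ``y`` — a
    deterministic surrogate for an adaptive smoothing rule.
    """
    if not isinstance(spec, str):
        if not spec > 0:
            raise InvalidParameterError("alpha must be positive")
        return float(spec)
    if spec != "auto":
        raise InvalidParameterError(f"alpha must be positive or 'auto', got {spec!r}")
    if y is None or k is None:
        raise InvalidParameterError("'auto' alpha needs a training sequence and order k")
    model = train(y, k, alpha=1.0)
    return _resolve_auto(model, y)
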