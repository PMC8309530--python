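"""Turn a raw single-lead ECG into a symbol sequence.

The pipeline is: zero-phase Butterworth low-pass filtering, first
differencing (which suppresses baseline wander), and equal-frequency
quantization of the differences into a small alphabet.  The quantizer is
always fit on the series it will quantize, so training and test material
never share quantizer state.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import DegenerateDistributionError, InvalidInputError, InvalidParameterError

__all__ = [
    "RawECG",
    "DiffSeries",
    "QuantizerModel",
    "SymbolSequence",
    "PrepConfig",
    "default_alphabet",
    "lowpass_filter",
    "difference",
    "fit_quantizer",
    "quantize",
    "prepare",
]

# Capital letters first, then lower case and digits for alphabets > 26.
_ALPHABET_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


def default_alphabet(size: int) -> tuple[str, ...]:
    """Ordered symbol alphabet of the given size (``A``, ``B``, ... by default)."""
    if size < 2:
        raise InvalidParameterError("alphabet size must be >= 2")
    if size > len(_ALPHABET_POOL):
        raise InvalidParameterError(
            f"alphabet size {size} exceeds the printable pool ({len(_ALPHABET_POOL)})"
        )
    return tuple(_ALPHABET_POOL[:size])


@dataclass(frozen=True)
class RawECG:
    """A sampled voltage series plus its acquisition labels.

    ``samples`` are in arbitrary voltage units (the pipeline is invariant to
    positive rescaling); ``fs`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float = 500.0
    subject_id: str = ""
    session: int = 1
    placement: str = "chest"
    condition: str = "rest"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise InvalidInputError("RawECG requires a non-empty sample series")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("RawECG samples must all be finite")
        if not self.fs > 0:
            raise InvalidParameterError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class DiffSeries:
    """First differences of a (filtered) ECG; input to the quantizer."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class QuantizerModel:
    """Equal-frequency quantizer: ordered breakpoints onto a finite alphabet.

    ``breakpoints`` are strictly increasing; values in the half-open interval
    ``[b[j-1], b[j])`` map to ``alphabet[j]`` and a value equal to a
    breakpoint goes to the upper interval.
    """

    alphabet: tuple[str, ...]
    breakpoints: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(self.alphabet) != bp.size + 1:
            raise InvalidParameterError("|alphabet| must equal |breakpoints| + 1")
        if bp.size and not np.all(np.diff(bp) > 0):
            raise InvalidParameterError("breakpoints must be strictly increasing")


@dataclass(frozen=True)
class SymbolSequence:
    """A string over a finite alphabet; the unit of compression.

    ``codes`` holds the same sequence as 0-based symbol indices, which is the
    representation the coder works with.
    """

    symbols: str
    alphabet: tuple[str, ...]
    codes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if self.codes is None:
            lut = {c: i for i, c in enumerate(self.alphabet)}
            try:
                codes = np.fromiter(
                    (lut[c] for c in self.symbols), dtype=np.uint8, count=len(self.symbols)
                )
            except KeyError as exc:
                raise InvalidInputError(f"symbol {exc.args[0]!r} outside alphabet") from exc
            object.__setattr__(self, "codes", codes)
        else:
            codes = np.asarray(self.codes, dtype=np.uint8)
            object.__setattr__(self, "codes", codes)
            if codes.size and codes.max() >= len(self.alphabet):
                raise InvalidInputError("symbol code outside alphabet")

    @classmethod
    def from_codes(cls, codes: np.ndarray, alphabet: tuple[str, ...]) -> "SymbolSequence":
        codes = np.asarray(codes, dtype=np.uint8)
        symbols = "".join(alphabet[c] for c in codes)
        return cls(symbols=symbols, alphabet=tuple(alphabet), codes=codes)

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet)

    def __len__(self) -> int:
        return self.codes.size


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing defaults: order-8 Butterworth at 40 Hz, 20 symbols."""

    filter_order: int = 8
    cutoff_hz: float = 40.0
    alphabet_size: int = 20
    allow_degenerate: bool = False


def lowpass_filter(ecg: RawECG, order: int = 8, cutoff: float = 40.0) -> RawECG:
    """Zero-phase Butterworth low-pass filter; labels and length preserved.

    Forward-backward application squares the magnitude response, so the
    stop-band attenuation is doubled in dB relative to a single pass.
    """
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not 0 < cutoff < ecg.fs / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={ecg.fs / 2} Hz)"
        )
    sos = _sig.butter(order, cutoff, btype="low", fs=ecg.fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, ecg.samples)
    return replace(ecg, samples=filtered)


def difference(ecg: RawECG) -> DiffSeries:
    """Consecutive differences ``x[i+1] - x[i]``; length ``n - 1``."""
    if ecg.samples.size < 2:
        raise InvalidInputError("differencing requires at least 2 samples")
    return DiffSeries(np.diff(ecg.samples))


def fit_quantizer(
    series: DiffSeries,
    alphabet_size: int = 20,
    allow_degenerate: bool = False,
) -> QuantizerModel:
    """Learn equal-frequency breakpoints from a difference series.

    Breakpoints are linear-interpolation empirical quantiles at probabilities
    ``j / |A|``, so each output symbol covers approximately the same sample
    mass on the training series.  Coincident quantiles (near-constant input)
    raise :class:`DegenerateDistributionError` unless ``allow_degenerate`` is
    set, in which case duplicates are collapsed with a warning and the
    alphabet shrinks accordingly.
    """
    if alphabet_size < 2:
        raise InvalidParameterError("alphabet_size must be >= 2")
    values = series.values
    if values.size < alphabet_size:
        raise InvalidInputError(
            f"series of length {values.size} too short for alphabet of {alphabet_size}"
        )
    probs = np.arange(1, alphabet_size) / alphabet_size
    breakpoints = np.quantile(values, probs, method="linear")
    if np.any(np.diff(breakpoints) <= 0) or breakpoints.size == 0:
        if not allow_degenerate:
            raise DegenerateDistributionError(
                "coincident quantile breakpoints (near-constant difference series); "
                "pass allow_degenerate=True to collapse them"
            )
        breakpoints = np.unique(breakpoints)
        warnings.warn(
            f"degenerate difference distribution: collapsed to "
            f"{breakpoints.size + 1} effective symbols",
            RuntimeWarning,
            stacklevel=2,
        )
    alphabet = default_alphabet(alphabet_size)[: breakpoints.size + 1]
    return QuantizerModel(alphabet=alphabet, breakpoints=breakpoints)


def quantize(series: DiffSeries, model: QuantizerModel) -> SymbolSequence:
    """Map each value to the symbol of the interval it falls in.

    Interval ``j`` is ``[b[j-1], b[j])``; a value equal to a breakpoint goes
    to the upper interval, and the last interval is closed above by +inf, so
    every real maps to some symbol.
    """
    idx = np.searchsorted(model.breakpoints, series.values, side="right")
    return SymbolSequence.from_codes(idx.astype(np.uint8), model.alphabet)


def prepare(ecg: RawECG, config: PrepConfig | None = None) -> SymbolSequence:
    """Full preprocessing: filter, difference, fit quantizer, quantize.

    The quantizer is fit on this recording's own difference series, so there
    is no cross-recording state and no train/test leakage.  Output length is
    always ``len(samples) - 1``.
    """
    config = config or PrepConfig()
    filtered = lowpass_filter(ecg, order=config.filter_order, cutoff=config.cutoff_hz)
    diffs = difference(filtered)
    model = fit_quantizer(
        diffs, alphabet_size=config.alphabet_size, allow_degenerate=config.allow_degenerate
    )
    return quantize(diffs, model)
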