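import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgid.errors import (
    DegenerateDistributionError,
    InvalidInputError,
    InvalidParameterError,
)
from ecgid.signal_prep import (
    DiffSeries,
    PrepConfig,
    QuantizerModel,
    RawECG,
    default_alphabet,
    difference,
    fit_quantizer,
    lowpass_filter,
    prepare,
    quantize,
)


def _ecg(samples, fs=500.0):
    return RawECG(samples=np.asarray(samples, dtype=float), fs=fs)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestLowpassFilter:
    def test_dc_passes_unchanged(self):
        out = lowpass_filter(_ecg(np.full(2000, 5.0)), order=8, cutoff=40.0)
        assert out.samples.shape == (2000,)
        np.testing.assert_allclose(out.samples, 5.0, rtol=1e-9)

    @pytest.mark.parametrize(
        "freq, keeps",
        [(5.0, True), (100.0, False)],  # passband vs deep stopband of 40 Hz cutoff
    )
    def test_sinusoid_attenuation(self, freq, keeps):
        t = np.arange(2000) / 500.0
        out = lowpass_filter(_ecg(np.sin(2 * np.pi * freq * t)), order=8, cutoff=40.0)
        # steady-state response: skip the filter's edge transients
        core = slice(200, -200)
        ratio = _rms(out.samples[core]) / _rms(np.sin(2 * np.pi * freq * t)[core])
        if keeps:
            assert abs(ratio - 1.0) < 0.01
        else:
            assert ratio < 0.01

    def test_labels_preserved(self):
        rec = RawECG(samples=np.random.default_rng(0).normal(size=1000), subject_id="S01",
                     session=2, placement="wrists", condition="move_feet")
        out = lowpass_filter(rec)
        assert (out.subject_id, out.session, out.placement, out.condition) == (
            "S01", 2, "wrists", "move_feet")

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            lowpass_filter(_ecg(np.zeros(100) + 1), order=8, cutoff=250.0)

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            _ecg([1.0, np.nan, 2.0])


class TestDifference:
    @pytest.mark.parametrize(
        "samples, expected",
        [
            ([1, 3, 2, 2], [2, -1, 0]),
            ([7, 7, 7, 7, 7], [0, 0, 0, 0]),
            (list(range(10)), [1] * 9),
        ],
    )
    def test_definition(self, samples, expected):
        np.testing.assert_array_equal(difference(_ecg(samples)).values, expected)

    def test_too_short(self):
        with pytest.raises(InvalidInputError):
            difference(_ecg([1.0]))


class TestFitQuantizer:
    def test_quartiles_of_ramp(self):
        series = DiffSeries(np.arange(1.0, 101.0))
        model = fit_quantizer(series, alphabet_size=4)
        assert model.breakpoints.size == 3
        np.testing.assert_allclose(model.breakpoints, [25.75, 50.5, 75.25])
        counts = np.bincount(quantize(series, model).codes, minlength=4)
        np.testing.assert_array_equal(counts, [25, 25, 25, 25])

    def test_equal_frequency_on_gaussian(self):
        values = np.random.default_rng(42).normal(size=1000)
        model = fit_quantizer(DiffSeries(values), alphabet_size=20)
        counts = np.bincount(quantize(DiffSeries(values), model).codes, minlength=20)
        assert counts.min() >= 49 and counts.max() <= 51

    def test_degenerate_raises_by_default(self):
        with pytest.raises(DegenerateDistributionError):
            fit_quantizer(DiffSeries(np.zeros(50)), alphabet_size=3)

    def test_degenerate_collapses_with_warning(self):
        with pytest.warns(RuntimeWarning):
            model = fit_quantizer(DiffSeries(np.zeros(50)), alphabet_size=3,
                                  allow_degenerate=True)
        assert len(model.alphabet) == model.breakpoints.size + 1

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            fit_quantizer(DiffSeries(np.arange(10.0)), alphabet_size=1)
        with pytest.raises(InvalidInputError):
            fit_quantizer(DiffSeries(np.arange(5.0)), alphabet_size=10)


class TestQuantize:
    def test_one_value_per_interval(self):
        model = QuantizerModel(alphabet=("A", "B", "C"), breakpoints=np.array([-1.0, 1.0]))
        seq = quantize(DiffSeries(np.array([-5.0, 0.0, 5.0])), model)
        assert seq.symbols == "ABC"

    def test_breakpoint_tie_goes_to_upper_interval(self):
        model = QuantizerModel(alphabet=("A", "B", "C"), breakpoints=np.array([-1.0, 1.0]))
        assert quantize(DiffSeries(np.array([1.0])), model).symbols == "C"
        assert quantize(DiffSeries(np.array([-1.0])), model).symbols == "B"

    def test_training_occupancy_near_uniform(self):
        values = np.random.default_rng(7).normal(size=10000)
        model = fit_quantizer(DiffSeries(values), alphabet_size=20)
        counts = np.bincount(quantize(DiffSeries(values), model).codes, minlength=20)
        assert counts.max() - counts.min() <= 2

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=2))
    def test_monotone(self, pair):
        model = fit_quantizer(DiffSeries(np.linspace(-10, 10, 100)), alphabet_size=5)
        lo, hi = sorted(pair)
        codes = quantize(DiffSeries(np.array([lo, hi])), model).codes
        assert codes[0] <= codes[1]


class TestPrepare:
    def test_length_contract(self):
        rng = np.random.default_rng(3)
        rec = _ecg(rng.normal(size=5000))
        assert len(prepare(rec)) == 4999

    def test_deterministic(self):
        rec = _ecg(np.random.default_rng(4).normal(size=3000))
        a, b = prepare(rec), prepare(rec)
        assert a.symbols == b.symbols

    def test_amplitude_scale_invariance(self):
        rec = _ecg(np.random.default_rng(5).normal(size=4000))
        scaled = _ecg(rec.samples * 3.7)
        assert prepare(rec).symbols == prepare(scaled).symbols

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            prepare(_ecg(np.full(1000, 2.0)))

    def test_alphabet_size_config(self):
        rec = _ecg(np.random.default_rng(6).normal(size=2000))
        seq = prepare(rec, PrepConfig(alphabet_size=6))
        assert seq.alphabet == default_alphabet(6)
        assert set(seq.symbols) <= set("ABCDEF")
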