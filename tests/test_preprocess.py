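"""Segmentation, filtering, band decomposition and epoching."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elindex.preprocess import (
    BAND_EDGES_HZ,
    Annotation,
    RawSegment,
    Recording,
    butterworth_designed_magnitude,
    decompose_bands,
    epoch_split,
    lowpass_filter,
    segment_record,
)
from ._oracles import fft_band_energy

FS = 200.0


def _recording(n_s: float = 120.0, fs: float = FS, annotations=None, seed: int = 0):
    rng = np.random.default_rng(seed)
    n = round(n_s * fs)
    return Recording(
        subject_id="S01",
        c3=rng.standard_normal(n),
        c4=rng.standard_normal(n),
        fs=fs,
        annotations=annotations or [],
    )


def _segment(x, fs: float = FS) -> RawSegment:
    return RawSegment("S01", "C3", "normal", x, fs, len(x) / fs)


class TestSegmentRecord:
    def test_event_locked_20s_window_has_4000_samples(self):
        rec = _recording(annotations=[Annotation("OSA", 100.0, 20.0)])
        c3, c4 = segment_record(rec, "OSA", window_s=20.0)
        assert len(c3.samples) == len(c4.samples) == 4000
        assert (c3.channel, c4.channel) == ("C3", "C4")
        assert c3.condition == "OSA"
        start = round(100.0 * FS)
        np.testing.assert_array_equal(c3.samples, rec.c3[start : start + 4000])

    def test_missing_event_and_degenerate_window(self):
        rec = _recording(annotations=[Annotation("normal", 10.0, 20.0)])
        with pytest.raises(ValueError, match="event not found"):
            segment_record(rec, "OSA")
        with pytest.raises(ValueError, match="window out of bounds"):
            segment_record(rec, "normal", window_s=0.0)

    def test_window_overrunning_recording_end(self):
        rec = _recording(n_s=30.0, annotations=[Annotation("OSA", 15.0, 10.0)])
        with pytest.raises(ValueError, match="window out of bounds"):
            segment_record(rec, "OSA", window_s=20.0)

    def test_annotation_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="outside the recording"):
            _recording(n_s=30.0, annotations=[Annotation("OSA", 25.0, 20.0)])


class TestLowpassFilter:
    def test_designed_magnitude_at_cutoff_is_minus_3dB(self):
        (mag,) = butterworth_designed_magnitude([50.0], cutoff_hz=50.0, order=8)
        assert mag == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-9)

    def test_designed_magnitude_matches_closed_form_in_stopband(self):
        # |H(f)| = (1 + (f/fc)^(2*order))^(-1/2) at 80 Hz, fc=50, order 8
        (mag,) = butterworth_designed_magnitude([80.0], cutoff_hz=50.0, order=8)
        assert mag == pytest.approx((1.0 + 1.6**16) ** -0.5, abs=1e-9)

    def test_dc_gain_is_unity_in_steady_state(self):
        seg = _segment(np.full(4000, 3.7))
        out = lowpass_filter(seg)
        # interior samples, away from edge transients
        np.testing.assert_allclose(out.samples[500:-500], 3.7, rtol=1e-6)

    def test_linearity(self, rng):
        x, y = rng.standard_normal(4000), rng.standard_normal(4000)
        a, b = 2.5, -1.25
        lhs = lowpass_filter(_segment(a * x + b * y)).samples
        rhs = a * lowpass_filter(_segment(x)).samples + b * lowpass_filter(_segment(y)).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_invalid_inputs(self):
        seg = _segment(np.zeros(4000))
        with pytest.raises(ValueError, match="invalid cutoff"):
            lowpass_filter(seg, cutoff_hz=100.0)
        bad = np.zeros(4000)
        bad[17] = np.nan
        with pytest.raises(ValueError, match="invalid signal"):
            _segment(bad)


class TestDecomposeBands:
    @pytest.mark.parametrize(
        "freq,band", [(2.0, "delta"), (5.5, "theta"), (10.5, "alpha"), (22.0, "beta")]
    )
    def test_band_center_sinusoid_fidelity(self, freq, band):
        """A band-center sinusoid keeps >= 0.85 of summed four-band energy
        in its own band, consistent with the FFT-mask oracle."""
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * freq * t)
        bands = decompose_bands(_segment(x)).bands
        energies = {k: float(np.sum(v**2)) for k, v in bands.items()}
        share = energies[band] / sum(energies.values())
        assert share >= 0.85
        lo, hi = BAND_EDGES_HZ[band]
        oracle = fft_band_energy(x, FS, lo, hi)
        assert energies[band] == pytest.approx(oracle, rel=0.1)

    def test_out_of_band_rejection_45hz(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 45.0 * t)
        bands = decompose_bands(_segment(x)).bands
        assert np.sum(bands["delta"] ** 2) < 0.05 * np.sum(x**2)

    def test_zero_input_gives_zero_bands(self):
        bands = decompose_bands(_segment(np.zeros(4000))).bands
        for sig in bands.values():
            np.testing.assert_array_equal(sig, 0.0)

    def test_fir_backend_fidelity(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 10.5 * t)
        bands = decompose_bands(_segment(x), backend="fir").bands
        energies = {k: float(np.sum(v**2)) for k, v in bands.items()}
        assert energies["alpha"] / sum(energies.values()) >= 0.85

    def test_invalid_band_tables(self):
        seg = _segment(np.zeros(4000))
        with pytest.raises(ValueError, match="invalid band table"):
            decompose_bands(seg, band_edges={"lo": (1.0, 8.0), "hi": (5.0, 30.0)})
        with pytest.raises(ValueError, match="invalid band table"):
            decompose_bands(seg, band_edges={"hf": (30.0, 150.0)})


class TestEpochSplit:
    def test_default_segmentation_yields_20_one_second_epochs(self):
        epochs = epoch_split(np.arange(4000.0), FS, epoch_s=1.0)
        assert len(epochs) == 20
        assert all(len(e.samples) == 200 for e in epochs)
        assert [e.index for e in epochs] == list(range(20))

    def test_ragged_length_rejected(self):
        with pytest.raises(ValueError, match="ragged epoching"):
            epoch_split(np.zeros(4001), FS)

    @settings(max_examples=25, derandomize=True)
    @given(n_epochs=st.integers(1, 12), epoch_len=st.integers(1, 50), seed=st.integers(0, 2**16))
    def test_partition_identity(self, n_epochs, epoch_len, seed):
        """Concatenating the epochs reproduces the input exactly."""
        x = np.random.default_rng(seed).standard_normal(n_epochs * epoch_len)
        epochs = epoch_split(x, fs=epoch_len, epoch_s=1.0)
        np.testing.assert_array_equal(np.concatenate([e.samples for e in epochs]), x)


def test_epoch_bookkeeping_160_per_subject_per_condition(small_cohort_features):
    """S subjects x 2 channels x 4 bands x 20 epochs = 160*S epochs per condition."""
    epoch_df, _ = small_cohort_features
    counts = epoch_df.groupby("condition").size()
    assert (counts == 160 * 3).all()
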