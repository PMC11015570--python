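"""Filtering, epoching and artifact-rejection contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restband.preprocess import (
    EpochSet,
    FilterSpec,
    bandpass_filter,
    epoch,
    n_epochs_expected,
    notch_filter,
    reject_artifacts,
)
from restband.recording import Recording

from conftest import central_amplitude, sine_recording


def brute_force_epoch_count(n: int, length: int, step: int) -> int:
    """Window enumerator: count starts with a full window inside the record."""
    count = 0
    start = 0
    while start + length <= n:
        count += 1
        start += step
    return count


class TestBandpass:
    def test_midband_sinusoid_passes_with_zero_phase(self):
        rec = sine_recording(10.0)
        out = bandpass_filter(rec).samples[0]
        # dual-pass gain of this design at 10 Hz is |H(10)|^2 ~= 0.989
        assert central_amplitude(out, 10.0, 1000.0) == pytest.approx(0.9893, abs=0.005)
        # zero phase: in-band output stays aligned with the input
        sl = slice(2500, 7500)
        corr = np.corrcoef(rec.samples[0][sl], out[sl])[0, 1]
        assert corr > 0.999

    def test_cutoff_amplitude_gain_is_half(self):
        # -3 dB per pass at the 30 Hz Butterworth edge, squared by the second pass
        out = bandpass_filter(sine_recording(30.0)).samples[0]
        assert central_amplitude(out, 30.0, 1000.0) == pytest.approx(0.5, rel=0.01)

    def test_dc_is_removed(self):
        rec = sine_recording(10.0, amplitude=0.0)
        rec.samples[:] = 100.0
        out = bandpass_filter(rec).samples[0]
        assert np.abs(out[2500:7500]).max() < 1.0

    def test_linearity(self):
        x = sine_recording(8.0, amplitude=1.0)
        y = sine_recording(20.0, amplitude=1.0)
        combo = x.copy_with(2.0 * x.samples + 3.0 * y.samples)
        lhs = bandpass_filter(combo).samples
        rhs = 2.0 * bandpass_filter(x).samples + 3.0 * bandpass_filter(y).samples
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_time_symmetric_input_gives_time_symmetric_output(self):
        # zero-phase property: dual-pass commutes with time reversal. A 1 Hz
        # high-pass corner keeps the startup transient short enough that the
        # record's core reaches steady state (the 0.1 Hz default decays over
        # several seconds, masking the symmetry in a 10 s record).
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 10000)
        x = x + x[::-1]  # symmetric
        rec = Recording("s", "c", 1000.0, ["Fz"], x[None, :])
        out = bandpass_filter(rec, FilterSpec(band_low=1.0)).samples[0]
        core = out[2000:-2000]
        assert np.allclose(core, core[::-1], atol=1e-3)

    def test_band_edge_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(sine_recording(10.0), FilterSpec(band_high=600.0))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(sine_recording(10.0, duration_s=1.0))


class TestNotch:
    def test_60hz_suppressed(self):
        out = notch_filter(sine_recording(60.0)).samples[0]
        assert central_amplitude(out, 60.0, 1000.0) <= 0.1

    def test_out_of_notch_identity(self):
        out = notch_filter(sine_recording(10.0)).samples[0]
        assert central_amplitude(out, 10.0, 1000.0) == pytest.approx(1.0, rel=0.01)

    def test_superposition(self):
        a = sine_recording(10.0)
        b = sine_recording(60.0)
        combo = a.copy_with(a.samples + b.samples)
        out = notch_filter(combo).samples[0]
        clean = notch_filter(a).samples[0]
        sl = slice(2500, 7500)
        assert np.allclose(out[sl], clean[sl], atol=0.02)

    def test_narrowness_per_pass(self):
        # one notch bandwidth (2 Hz) away the single-pass loss is under 1 dB
        from scipy import signal

        spec = FilterSpec()
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=1000.0)
        _, h = signal.freqz(b, a, worN=[58.0, 62.0], fs=1000.0)
        db = 20 * np.log10(np.abs(h))
        assert (db > -1.0).all()


class TestEpoching:
    def test_five_minute_block_yields_599_epochs(self):
        rec = sine_recording(10.0, duration_s=300.0)
        assert epoch(rec, 1000.0, 500.0).n_epochs == 599

    @pytest.mark.parametrize(
        "n_samples, expected",
        [(1000, 1), (1499, 1), (1500, 2), (999, 0)],
    )
    def test_boundary_counts(self, n_samples, expected):
        rec = Recording("s", "c", 1000.0, ["Fz"], np.zeros((1, n_samples)))
        if expected == 0:
            with pytest.raises(ValueError, match="shorter than one"):
                epoch(rec, 1000.0, 500.0)
        else:
            assert epoch(rec, 1000.0, 500.0).n_epochs == expected

    @given(
        n=st.integers(min_value=1, max_value=5000),
        length=st.integers(min_value=1, max_value=2000),
        step=st.integers(min_value=1, max_value=2000),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_count_formula_matches_enumerator(self, n, length, step):
        assert n_epochs_expected(n, length, step) == brute_force_epoch_count(n, length, step)

    def test_epoch_starts_and_content(self):
        x = np.arange(3000, dtype=float)
        rec = Recording("s", "c", 1000.0, ["Fz"], x[None, :])
        eps = epoch(rec, 1000.0, 500.0)
        assert eps.n_epochs == 5
        for k in range(5):
            assert eps.epochs[k, 0, 0] == 500.0 * k  # start sample k*step
            assert eps.epochs[k, 0, -1] == 500.0 * k + 999

    def test_invalid_overlap(self):
        rec = sine_recording(10.0)
        with pytest.raises(ValueError, match="overlap"):
            epoch(rec, 1000.0, 1000.0)


class TestRejection:
    def _epochs_from(self, arr: np.ndarray) -> EpochSet:
        """One-channel EpochSet with the given (n_epochs, samples) data."""
        arr = np.asarray(arr, dtype=float)[:, None, :]
        return EpochSet(
            subject_id="s",
            condition="c",
            sampling_rate=1000.0,
            channel_labels=["Fz"],
            epoch_length_ms=arr.shape[2],
            overlap_ms=0.0,
            epochs=arr,
            reject_mask=np.zeros(arr.shape[:2], dtype=bool),
        )

    def test_peak_to_peak_decisions(self):
        eps = self._epochs_from(
            [
                np.zeros(100),  # ptp 0 -> kept
                np.linspace(-100.0, 60.0, 100),  # ptp 160 -> rejected
                np.linspace(0.0, 150.0, 100),  # ptp exactly 150 -> kept (strict >)
            ]
        )
        out = reject_artifacts(eps, 150.0)
        assert out.reject_mask[:, 0].tolist() == [False, True, False]
        assert np.array_equal(out.epochs, eps.epochs)  # data untouched

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        eps = self._epochs_from(rng.normal(0, 60, (50, 200)))
        low = reject_artifacts(eps, 100.0).reject_mask.sum()
        high = reject_artifacts(eps, 200.0).reject_mask.sum()
        assert high <= low

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 60, (20, 200))
        base = reject_artifacts(self._epochs_from(data), 150.0).reject_mask
        shifted = reject_artifacts(self._epochs_from(data + 500.0), 150.0).reject_mask
        assert np.array_equal(base, shifted)

    def test_epoch_scope_spreads_across_channels(self):
        data = np.zeros((2, 2, 100))
        data[0, 1, 0] = 200.0  # epoch 0 bad on channel 2 only
        eps = EpochSet(
            subject_id="s",
            condition="c",
            sampling_rate=1000.0,
            channel_labels=["Fz", "Cz"],
            epoch_length_ms=100,
            overlap_ms=0,
            epochs=data,
            reject_mask=np.zeros((2, 2), dtype=bool),
        )
        per_channel = reject_artifacts(eps, 150.0, scope="channel")
        assert per_channel.reject_mask.tolist() == [[False, True], [False, False]]
        whole = reject_artifacts(eps, 150.0, scope="epoch")
        assert whole.reject_mask.tolist() == [[True, True], [False, False]]

    def test_successive_difference_mode(self):
        # slow ramp spanning 200 uV: large ptp but tiny successive steps
        ramp = np.linspace(0.0, 200.0, 1000)
        eps = self._epochs_from([ramp])
        assert reject_artifacts(eps, 150.0).reject_mask[0, 0]
        assert not reject_artifacts(eps, 150.0, criterion="successive_difference").reject_mask[0, 0]

    def test_bad_threshold(self):
        eps = self._epochs_from([np.zeros(10)])
        with pytest.raises(ValueError):
            reject_artifacts(eps, 0.0)
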