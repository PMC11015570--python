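"""Filtering, epoching and artifact rejection for continuous EEG.

The preprocessing chain is the conventional one for resting-state band-power
analysis: a zero-phase (dual-pass) Butterworth band-pass, a narrow mains
notch, segmentation into overlapping fixed-length epochs, and per-channel
peak-to-peak artifact rejection.

Dual-pass filtering applies the filter forward and then backward in time
(:func:`scipy.signal.sosfiltfilt`), which cancels phase distortion and
squares the single-pass magnitude response — so a Butterworth band edge,
−3 dB per pass, has amplitude gain 0.5 after both passes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass_filter",
    "notch_filter",
    "epoch",
    "reject_artifacts",
    "n_epochs_expected",
]

#: Minimum recording length (s) accepted by the filters; shorter blocks are
#: dominated by the dual-pass startup transient.
MIN_FILTER_DURATION_S = 3.0


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch filter parameters.

    Defaults follow standard resting-EEG practice: 0.1–30 Hz Butterworth
    pass-band, second order per pass, applied forward–backward (zero phase),
    with a narrow 60 Hz mains notch (−3 dB bandwidth 2 Hz, i.e. Q = 30).
    """

    band_low: float = 0.1
    band_high: float = 30.0
    order_per_pass: int = 2
    notch_freq: float = 60.0
    notch_bandwidth: float = 2.0
    dual_pass: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if self.band_high >= nyq:
            raise ValueError(
                f"band_high {self.band_high} Hz at or above Nyquist ({nyq} Hz)"
            )
        if self.order_per_pass < 1:
            raise ValueError("order_per_pass must be >= 1")
        if self.notch_freq >= nyq:
            raise ValueError(
                f"notch_freq {self.notch_freq} Hz at or above Nyquist ({nyq} Hz)"
            )
        if self.notch_bandwidth <= 0:
            raise ValueError("notch_bandwidth must be > 0")

    @property
    def notch_q(self) -> float:
        """Notch quality factor (centre frequency / −3 dB bandwidth)."""
        return self.notch_freq / self.notch_bandwidth


def _check_length(rec: Recording) -> None:
    if rec.duration < MIN_FILTER_DURATION_S:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is too short for stable "
            f"dual-pass filtering (need >= {MIN_FILTER_DURATION_S} s)"
        )


def bandpass_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth band-pass of a recording.

    A single band-pass design of order ``spec.order_per_pass`` is applied
    forward and backward (second-order sections for numerical stability at
    low band edges). Returns a new :class:`Recording` of the same shape.
    """
    spec.validate(rec.sampling_rate)
    _check_length(rec)
    sos = signal.butter(
        spec.order_per_pass,
        [spec.band_low, spec.band_high],
        btype="bandpass",
        output="sos",
        fs=rec.sampling_rate,
    )
    if spec.dual_pass:
        out = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    else:
        out = signal.sosfilt(sos, rec.samples, axis=-1)
    return rec.copy_with(out)


def notch_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase narrow notch at ``spec.notch_freq`` (mains suppression)."""
    spec.validate(rec.sampling_rate)
    _check_length(rec)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=rec.sampling_rate)
    if spec.dual_pass:
        out = signal.filtfilt(b, a, rec.samples, axis=-1)
    else:
        out = signal.lfilter(b, a, rec.samples, axis=-1)
    return rec.copy_with(out)


def n_epochs_expected(n_samples: int, epoch_samples: int, step_samples: int) -> int:
    """Number of full epochs: floor((N − L)/S) + 1, 0 if N < L."""
    if n_samples < epoch_samples:
        return 0
    return (n_samples - epoch_samples) // step_samples + 1


@dataclass
class EpochSet:
    """Overlapping fixed-length epochs of one recording.

    ``epochs`` is an (n_epochs, n_channels, epoch_samples) array in μV.
    ``reject_mask[k, c]`` is True where epoch ``k`` on channel ``c`` has been
    marked as an artifact; freshly built sets start with nothing rejected.
    """

    subject_id: str
    condition: str
    sampling_rate: float
    channel_labels: list[str]
    epoch_length_ms: float
    overlap_ms: float
    epochs: np.ndarray
    reject_mask: np.ndarray
    reject_threshold_uv: float | None = None

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_samples(self) -> int:
        return self.epochs.shape[2]

    def channel_index(self, label: str) -> int:
        from .recording import normalize_label

        want = normalize_label(label)
        for i, c in enumerate(self.channel_labels):
            if normalize_label(c) == want:
                return i
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")

    def retained(self, channel: str) -> np.ndarray:
        """Retained (non-rejected) epochs on one channel: (n_kept, L) array."""
        c = self.channel_index(channel)
        keep = ~self.reject_mask[:, c]
        return self.epochs[keep, c, :]

    def n_retained(self, channel: str) -> int:
        c = self.channel_index(channel)
        return int((~self.reject_mask[:, c]).sum())

    def retained_counts(self) -> dict[str, int]:
        return {ch: self.n_retained(ch) for ch in self.channel_labels}


def epoch(rec: Recording, length_ms: float = 1000.0, overlap_ms: float = 500.0) -> EpochSet:
    """Segment a recording into overlapping epochs.

    Epoch k covers samples ``[k*S, k*S + L)`` with ``L = round(length_ms *
    fs / 1000)`` and step ``S = L − overlap_samples``; a trailing partial
    window is discarded.
    """
    if not 0 <= overlap_ms < length_ms:
        raise ValueError(f"need 0 <= overlap_ms < length_ms, got {overlap_ms}, {length_ms}")
    L = int(round(length_ms * rec.sampling_rate / 1000.0))
    overlap = int(round(overlap_ms * rec.sampling_rate / 1000.0))
    S = L - overlap
    if L < 1 or S < 1:
        raise ValueError("epoch length and step must be at least one sample")
    n = n_epochs_expected(rec.n_samples, L, S)
    if n == 0:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{L}-sample epoch"
        )
    # strided view -> copy keeps EpochSet independent of the recording buffer
    starts = np.arange(n) * S
    idx = starts[:, None] + np.arange(L)[None, :]
    epochs = rec.samples[:, idx].transpose(1, 0, 2).copy()
    return EpochSet(
        subject_id=rec.subject_id,
        condition=rec.condition,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
        epoch_length_ms=length_ms,
        overlap_ms=overlap_ms,
        epochs=epochs,
        reject_mask=np.zeros((n, rec.n_channels), dtype=bool),
    )


def reject_artifacts(
    epochs: EpochSet,
    threshold_uv: float = 150.0,
    scope: str = "channel",
    criterion: str = "peak_to_peak",
) -> EpochSet:
    """Mark epochs whose within-epoch amplitude range exceeds a threshold.

    The default criterion is peak-to-peak: max − min within the epoch
    strictly greater than ``threshold_uv`` rejects the (epoch, channel) cell.
    ``criterion="successive_difference"`` instead thresholds the largest
    absolute sample-to-sample step, an alternative reading of an
    "absolute difference" criterion. With ``scope="channel"`` (default)
    rejection is per channel — an epoch rejected on Cz still contributes to
    Fz averages; ``scope="epoch"`` rejects the whole epoch on all channels
    if any channel exceeds the threshold. Epoch data are unchanged.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be > 0")
    if scope not in ("channel", "epoch"):
        raise ValueError(f"scope must be 'channel' or 'epoch', got {scope!r}")
    if criterion == "peak_to_peak":
        stat = epochs.epochs.max(axis=-1) - epochs.epochs.min(axis=-1)
    elif criterion == "successive_difference":
        stat = np.abs(np.diff(epochs.epochs, axis=-1)).max(axis=-1)
    else:
        raise ValueError(f"unknown rejection criterion {criterion!r}")
    mask = stat > threshold_uv
    if scope == "epoch":
        mask = np.broadcast_to(mask.any(axis=1)[:, None], mask.shape).copy()
    return replace(
        epochs,
        epochs=epochs.epochs,
        reject_mask=mask,
        reject_threshold_uv=threshold_uv,
    )
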