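"""FFT power spectra and band-power extraction.

Per-epoch spectra use a plain (rectangular-window) FFT of the demeaned
epoch, with a single-sided normalization fixed so a bin-aligned sinusoid of
amplitude A carries A²/2 μV² at its bin. Spectra are averaged arithmetically
over retained epochs, and band power is the mean of the averaged power over
the bins inside a named band, inclusive of both edges.

With the standard 1000-sample epochs at 1 kHz the grid resolution is
Δf = 1 Hz, so the default bands cover 4 (theta), 5 (alpha) and 18 (beta)
bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet, FilterSpec, bandpass_filter, epoch, notch_filter, reject_artifacts
from .recording import StudyDataset

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "DEFAULT_CHANNELS",
    "PowerSpectrum",
    "BandPowerTable",
    "epoch_power_spectrum",
    "band_power",
    "compute_band_power_table",
    "single_sided_power",
]

logger = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz")


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band, inclusive on both edges (Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"band {self.name}: low {self.low} > high {self.high}")


#: Conventional resting-EEG bands of interest. Delta (1–3 Hz) is deliberately
#: not analyzed by default; arbitrary bands may be supplied instead.
DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
)


def single_sided_power(x: np.ndarray, demean: bool = True, window: str = "rect") -> np.ndarray:
    """Single-sided power spectrum of epochs along the last axis (μV²).

    Normalized so a bin-aligned sinusoid of amplitude A yields A²/2 at its
    bin, and so the sum over all bins equals the time-domain mean square
    (Parseval). ``window="hann"`` applies a Hann taper with amplitude-
    preserving (coherent-gain) normalization, provided for sensitivity
    analysis; the default is the raw rectangular-window transform.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if demean:
        x = x - x.mean(axis=-1, keepdims=True)
    if window == "hann":
        w = np.hanning(n)
        x = x * (w / w.mean())
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(x, axis=-1) / n
    power = np.abs(spec) ** 2
    # double the paired bins (all but DC, and Nyquist when n is even)
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    return power


@dataclass
class PowerSpectrum:
    """Epoch-averaged single-sided power per channel on a discrete grid.

    ``power`` is (n_channels, n_freqs) in μV²; ``freqs`` runs 0..Nyquist
    with resolution sampling_rate / epoch_samples. ``n_epochs_averaged``
    records, per channel, how many retained epochs went into the average.
    """

    channel_labels: list[str]
    freqs: np.ndarray
    power: np.ndarray
    n_epochs_averaged: dict[str, int]

    def channel_power(self, label: str) -> np.ndarray:
        from .recording import normalize_label

        want = normalize_label(label)
        for i, c in enumerate(self.channel_labels):
            if normalize_label(c) == want:
                return self.power[i]
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")


def epoch_power_spectrum(
    epochs: EpochSet,
    channels: Sequence[str] | None = None,
    demean: bool = True,
    window: str = "rect",
) -> PowerSpectrum:
    """Average per-epoch power spectra over retained epochs, per channel.

    Raises a degenerate-input error if a requested channel has zero
    retained epochs.
    """
    chans = list(channels) if channels is not None else list(epochs.channel_labels)
    n = epochs.epoch_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.sampling_rate)
    power = np.empty((len(chans), freqs.size))
    counts: dict[str, int] = {}
    for i, ch in enumerate(chans):
        kept = epochs.retained(ch)
        if kept.shape[0] == 0:
            raise ValueError(
                f"no retained epochs on channel {ch} "
                f"(subject {epochs.subject_id}, condition {epochs.condition})"
            )
        power[i] = single_sided_power(kept, demean=demean, window=window).mean(axis=0)
        counts[ch] = kept.shape[0]
    return PowerSpectrum(
        channel_labels=chans, freqs=freqs, power=power, n_epochs_averaged=counts
    )


def band_power(
    spectrum: PowerSpectrum,
    band: BandDefinition,
    channel: str,
    aggregate: str = "mean",
) -> float:
    """Band power in μV²: mean (or sum) of power over bins with low ≤ f ≤ high."""
    sel = (spectrum.freqs >= band.low) & (spectrum.freqs <= band.high)
    if not sel.any():
        raise ValueError(
            f"no frequency bins inside band {band.name} [{band.low}, {band.high}] Hz "
            f"at resolution {spectrum.freqs[1] - spectrum.freqs[0]:g} Hz"
        )
    p = spectrum.channel_power(channel)[sel]
    if aggregate == "mean":
        return float(p.mean())
    if aggregate == "sum":
        return float(p.sum())
    raise ValueError(f"unknown band aggregate {aggregate!r}")


@dataclass
class BandPowerTable:
    """Long-format subject × condition × channel × band power table.

    ``data`` has columns subject_id, condition, channel, band, power_uv2,
    n_epochs — one row per combination. This is the statistics layer's
    input; :meth:`condition_summary` yields the per-condition mean (M) and
    standard deviation (SD) across subjects for one (band, channel) cell.
    """

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject_id", "condition", "channel", "band", "power_uv2", "n_epochs"]
        )
    )

    COLUMNS = ("subject_id", "condition", "channel", "band", "power_uv2", "n_epochs")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"band-power table missing columns {missing}")
        if len(self.data) and (self.data["power_uv2"] < 0).any():
            raise ValueError("band power must be non-negative")
        dup = self.data.duplicated(subset=["subject_id", "condition", "channel", "band"])
        if dup.any():
            raise ValueError("duplicate (subject, condition, channel, band) rows")

    def __len__(self) -> int:
        return len(self.data)

    def sorted(self) -> "BandPowerTable":
        """Stable canonical row order: subject, condition, channel, band."""
        out = self.data.sort_values(
            ["subject_id", "condition", "channel", "band"], kind="mergesort"
        ).reset_index(drop=True)
        return BandPowerTable(out)

    def cell(self, band: str, channel: str) -> pd.DataFrame:
        """Rows of one (band, channel) cell."""
        d = self.data
        return d[(d["band"] == band) & (d["channel"] == channel)]

    def wide(self, band: str, channel: str) -> pd.DataFrame:
        """Subjects × conditions matrix of power for one (band, channel)."""
        return self.cell(band, channel).pivot(
            index="subject_id", columns="condition", values="power_uv2"
        )

    def condition_summary(self, band: str, channel: str) -> pd.DataFrame:
        """Per-condition M and SD across subjects for one (band, channel)."""
        g = self.cell(band, channel).groupby("condition")["power_uv2"]
        return pd.DataFrame({"M": g.mean(), "SD": g.std(ddof=1), "n": g.count()})

    @property
    def bands(self) -> list[str]:
        return list(pd.unique(self.data["band"]))

    @property
    def channels(self) -> list[str]:
        return list(pd.unique(self.data["channel"]))

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.data["condition"]))


def compute_band_power_table(
    study: StudyDataset,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    filter_spec: FilterSpec = FilterSpec(),
    epoch_length_ms: float = 1000.0,
    overlap_ms: float = 500.0,
    reject_threshold_uv: float = 150.0,
    reject_scope: str = "channel",
    conditions: Sequence[str] | None = None,
    window: str = "rect",
    band_aggregate: str = "mean",
    apply_filters: bool = True,
) -> BandPowerTable:
    """Full per-recording chain: filter → notch → epoch → reject → FFT → band power.

    Only subjects complete for the analyzed conditions enter the table
    (listwise deletion); dropped subjects are logged with the reason.
    Deterministic given inputs and configuration.
    """
    conds = list(conditions) if conditions is not None else study.conditions
    complete = study.complete_subjects(conds)
    for s in study.incomplete_subjects(conds):
        logger.warning(
            "subject %s dropped: missing conditions %s",
            s,
            sorted(set(conds) - set(study.conditions_of(s))),
        )
    rows = []
    for sid in complete:
        for cond in conds:
            rec = study.get(sid, cond)
            if not rec.has_channels(channels):
                raise ValueError(
                    f"subject {sid}, condition {cond}: recording lacks "
                    f"required channels {list(channels)}"
                )
            if apply_filters:
                rec = notch_filter(bandpass_filter(rec, filter_spec), filter_spec)
            eps = epoch(rec, epoch_length_ms, overlap_ms)
            eps = reject_artifacts(eps, reject_threshold_uv, scope=reject_scope)
            logger.info(
                "subject %s, condition %s: retained epochs %s of %d",
                sid,
                cond,
                eps.retained_counts(),
                eps.n_epochs,
            )
            spectrum = epoch_power_spectrum(eps, channels=list(channels), window=window)
            for ch in channels:
                for b in bands:
                    rows.append(
                        {
                            "subject_id": sid,
                            "condition": cond,
                            "channel": ch,
                            "band": b.name,
                            "power_uv2": band_power(spectrum, b, ch, aggregate=band_aggregate),
                            "n_epochs": spectrum.n_epochs_averaged[ch],
                        }
                    )
    return BandPowerTable(pd.DataFrame(rows, columns=list(BandPowerTable.COLUMNS))).sorted()
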