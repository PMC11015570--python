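"""Synthetic resting-state EEG studies with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: band-limited oscillations superposed on 1/f background noise,
60 Hz line contamination, occasional high-amplitude transient artifacts,
multiplicative between-subject variability, and deterministic
condition-specific amplitude effects (by default, a reduction of frontal
beta power in the light-filtering-glasses condition).

Oscillations are sums of fixed-frequency random-phase sinusoids at the
band's integer frequencies. With 1000-sample epochs at 1 kHz these are
bin-aligned (Δf = 1 Hz), so the band-power ground truth is analytic: each
component of amplitude A contributes exactly A²/2 μV² at its bin, and the
band mean over bins equals A_eff²/2 when every in-band bin carries a
component of the same amplitude.

All randomness is keyed by stable SHA-256-derived child seeds of
``(master_seed, role, subject, condition, channel)`` — the same
configuration always produces bit-identical recordings, independent of
enumeration order and platform.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .recording import Recording, StudyDataset

__all__ = [
    "SimConfig",
    "simulate_recording",
    "simulate_study",
    "write_fixture_study",
    "derive_seed",
]

#: Default per-(channel, band) oscillation component amplitudes (μV).
#: Analytic band power (mean over bins) is A²/2; the frontal beta value is
#: set so its analytic power is ≈ 0.77 μV², with alpha dominant posteriorly
#: as in typical eyes-open resting EEG.
DEFAULT_BASE_AMPLITUDES: dict[tuple[str, str], float] = {
    ("Fz", "theta"): 1.40,
    ("Fz", "alpha"): 1.50,
    ("Fz", "beta"): math.sqrt(2 * 0.77),
    ("Cz", "theta"): 1.30,
    ("Cz", "alpha"): 1.70,
    ("Cz", "beta"): 1.20,
    ("Pz", "theta"): 1.20,
    ("Pz", "alpha"): 2.00,
    ("Pz", "beta"): 1.10,
}

#: Default deterministic condition multipliers on oscillation amplitude.
#: Frontal beta is attenuated in the lensed conditions so that the analytic
#: power ratios are ≈ 0.75/0.77 (clear control) and ≈ 0.65/0.77 (filtering
#: glasses) relative to the no-glasses baseline.
DEFAULT_CONDITION_EFFECTS: dict[tuple[str, str, str], float] = {
    ("Fz", "beta", "clear_glasses"): math.sqrt(0.75 / 0.77),
    ("Fz", "beta", "filter_glasses"): math.sqrt(0.65 / 0.77),
}

DEFAULT_BAND_RANGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}


def derive_seed(*parts: object) -> int:
    """Stable 31-bit child seed from a tuple of hashable parts."""
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic resting-state EEG study.

    Defaults emulate a three-condition eyes-open study: 40 subjects,
    five-minute blocks at 1 kHz on midline electrodes Fz/Cz/Pz, with a
    frontal-beta amplitude reduction in the lensed conditions.
    """

    n_subjects: int = 40
    conditions: tuple[str, ...] = ("no_glasses", "clear_glasses", "filter_glasses")
    duration_s: float = 300.0
    sampling_rate: float = 1000.0
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    band_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_RANGES)
    )
    base_amplitudes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_AMPLITUDES)
    )
    condition_effects: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    between_subject_sd: float = 0.2  # sigma of log amplitude factor
    pink_noise_scale: float = 3.0  # total RMS of the 1/f background, μV
    pink_exponent: float = 1.0  # power spectral slope: S(f) ∝ f^-exponent
    line_noise_amp: float = 5.0  # 60 Hz component amplitude, μV
    line_freq: float = 60.0
    artifact_rate: float = 2.0  # events per minute, Poisson
    artifact_amp: float = 300.0  # pulse peak, μV (> the 150 μV criterion)
    artifact_duration_ms: float = 200.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for name, val in (
            ("between_subject_sd", self.between_subject_sd),
            ("pink_noise_scale", self.pink_noise_scale),
            ("line_noise_amp", self.line_noise_amp),
            ("artifact_rate", self.artifact_rate),
            ("artifact_amp", self.artifact_amp),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")

    def subject_ids(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_subjects)]

    def subject_factor(self, subject_id: str) -> float:
        """Per-subject multiplicative lognormal amplitude factor."""
        if self.between_subject_sd == 0:
            return 1.0
        rng = np.random.default_rng(derive_seed(self.master_seed, "subject", subject_id))
        return float(np.exp(rng.normal(0.0, self.between_subject_sd)))

    def effective_amplitude(self, subject_id: str, condition: str, channel: str, band: str) -> float:
        """A_eff = base × condition multiplier × subject lognormal factor."""
        base = self.base_amplitudes.get((channel, band), 0.0)
        eff = self.condition_effects.get((channel, band, condition), 1.0)
        return base * eff * self.subject_factor(subject_id)

    def analytic_band_power(
        self, subject_id: str, condition: str, channel: str, band: str
    ) -> float:
        """Ground-truth oscillation band power (mean over bins): A_eff²/2 μV²."""
        a = self.effective_amplitude(subject_id, condition, channel, band)
        return a * a / 2.0

    def expected_noise_bin_power(self, freq_hz: float) -> float:
        """Expected 1/f background power in a 1 Hz-wide bin at ``freq_hz`` (μV²).

        Follows from the synthesis profile (power ∝ f^-exponent, normalized
        to total RMS ``pink_noise_scale`` over the full record).
        """
        if self.pink_noise_scale == 0:
            return 0.0
        n = int(round(self.duration_s * self.sampling_rate))
        freqs = np.fft.rfftfreq(n, d=1.0 / self.sampling_rate)[1:]
        total = (freqs ** (-self.pink_exponent)).sum()
        # density per Hz × 1 Hz bin width
        return float(
            self.pink_noise_scale**2 * freq_hz ** (-self.pink_exponent) / total * self.duration_s
        )


def _band_frequencies(low: float, high: float) -> np.ndarray:
    """Integer component frequencies spanning [low, high], inclusive."""
    return np.arange(math.ceil(low), math.floor(high) + 1, dtype=float)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, scale: float, exponent: float) -> np.ndarray:
    """Noise with power spectrum ∝ 1/f^exponent and expected total RMS ``scale`` μV."""
    if scale == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    # normalize so the expected time-domain variance equals scale²
    amp *= scale / np.sqrt(2.0 * (amp[1:] ** 2).sum())
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spec = amp * z
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec * n / np.sqrt(2.0), n=n)


def _raised_cosine_pulse(n: int) -> np.ndarray:
    """Unit-peak raised-cosine pulse of n samples (smooth onset/offset)."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def simulate_recording(config: SimConfig, subject_index: int, condition: str) -> Recording:
    """Synthesize one subject × condition recording.

    Per channel: sum over bands of A_eff-scaled random-phase sinusoids at
    the band's integer frequencies, plus 1/f noise, a 60 Hz line component,
    and Poisson-injected raised-cosine artifact pulses. Deterministic for a
    given (master_seed, subject, condition).
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}; have {list(config.conditions)}")
    subject_id = config.subject_ids()[subject_index]
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    data = np.zeros((len(config.channels), n))
    for ci, ch in enumerate(config.channels):
        x = np.zeros(n)
        for band, (low, high) in config.band_ranges.items():
            a_eff = config.effective_amplitude(subject_id, condition, ch, band)
            if a_eff == 0:
                continue
            rng = np.random.default_rng(
                derive_seed(config.master_seed, "osc", subject_id, condition, ch, band)
            )
            for f in _band_frequencies(low, high):
                phase = rng.uniform(0, 2 * np.pi)
                x += a_eff * np.sin(2 * np.pi * f * t + phase)
        noise_rng = np.random.default_rng(
            derive_seed(config.master_seed, "noise", subject_id, condition, ch)
        )
        x += _pink_noise(noise_rng, n, fs, config.pink_noise_scale, config.pink_exponent)
        if config.line_noise_amp > 0:
            line_rng = np.random.default_rng(
                derive_seed(config.master_seed, "line", subject_id, condition, ch)
            )
            x += config.line_noise_amp * np.sin(
                2 * np.pi * config.line_freq * t + line_rng.uniform(0, 2 * np.pi)
            )
        if config.artifact_rate > 0 and config.artifact_amp > 0:
            art_rng = np.random.default_rng(
                derive_seed(config.master_seed, "artifact", subject_id, condition, ch)
            )
            n_events = art_rng.poisson(config.artifact_rate * config.duration_s / 60.0)
            width = int(round(config.artifact_duration_ms * fs / 1000.0))
            pulse = config.artifact_amp * _raised_cosine_pulse(width)
            for _ in range(n_events):
                onset = int(art_rng.integers(0, max(n - width, 1)))
                x[onset : onset + width] += pulse[: n - onset]
        data[ci] = x
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sampling_rate=fs,
        channel_labels=list(config.channels),
        samples=data,
    )


def ground_truth(config: SimConfig) -> pd.DataFrame:
    """True effective amplitudes and analytic band powers per cell."""
    rows = []
    for sid in config.subject_ids():
        for cond in config.conditions:
            for ch in config.channels:
                for band in config.band_ranges:
                    a = config.effective_amplitude(sid, cond, ch, band)
                    rows.append(
                        {
                            "subject_id": sid,
                            "condition": cond,
                            "channel": ch,
                            "band": band,
                            "amplitude_uv": a,
                            "band_power_uv2": a * a / 2.0,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_study(config: SimConfig) -> tuple[StudyDataset, pd.DataFrame]:
    """Full study: all subject × condition recordings plus ground truth."""
    study = StudyDataset()
    for i, sid in enumerate(config.subject_ids()):
        for cond in config.conditions:
            study.add(simulate_recording(config, i, cond))
        study.metadata[sid] = {"subject_factor": config.subject_factor(sid)}
    return study, ground_truth(config)


def write_fixture_study(
    config: SimConfig, out_dir: str | Path, fmt: str = "csv"
) -> Path:
    """Serialize a simulated study to disk with an io-compatible manifest.

    Writes one recording file per (subject, condition) in ``fmt`` ("csv" or
    "edf"), a ``manifest.csv`` loadable by :func:`restband.io.load_study`,
    and a ``ground_truth.csv`` table. Returns the manifest path.
    """
    from . import io as rb_io  # deferred: io imports optional readers

    if fmt not in ("csv", "edf"):
        raise ValueError(f"format must be 'csv' or 'edf', got {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(config.subject_ids()):
        for cond in config.conditions:
            rec = simulate_recording(config, i, cond)
            fname = f"{sid}_{cond}.{fmt}"
            if fmt == "csv":
                rb_io.write_recording_csv(rec, out / fname)
            else:
                from .edf import write_edf

                write_edf(rec, out / fname)
            rows.append(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "path": fname,
                    "format": fmt,
                    "sampling_rate": config.sampling_rate,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    ground_truth(config).to_csv(out / "ground_truth.csv", index=False, float_format="%.17g")
    return manifest
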