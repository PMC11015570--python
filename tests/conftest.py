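import numpy as np
import pandas as pd
import pytest

from restband.recording import Recording
from restband.spectral import BandPowerTable
from restband.synthetic import SimConfig, simulate_study


def make_table(values: np.ndarray, band: str = "beta", channel: str = "Fz") -> BandPowerTable:
    """Band-power table from a subjects × conditions array of values."""
    values = np.asarray(values, dtype=float)
    n, j = values.shape
    rows = [
        {
            "subject_id": f"s{i:02d}",
            "condition": f"c{k}",
            "channel": channel,
            "band": band,
            "power_uv2": values[i, k],
            "n_epochs": 10,
        }
        for i in range(n)
        for k in range(j)
    ]
    return BandPowerTable(pd.DataFrame(rows))


def sine_recording(
    freq: float,
    amplitude: float = 1.0,
    duration_s: float = 10.0,
    fs: float = 1000.0,
    channels: tuple[str, ...] = ("Fz",),
) -> Recording:
    t = np.arange(int(round(duration_s * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return Recording("s1", "cond", fs, list(channels), np.tile(x, (len(channels), 1)))


def central_amplitude(x: np.ndarray, freq: float, fs: float) -> float:
    """Steady-state amplitude of a sinusoid via quadrature projection on the middle half."""
    n = x.size
    sl = slice(n // 4, 3 * n // 4)
    t = np.arange(n) / fs
    c = np.cos(2 * np.pi * freq * t[sl])
    s = np.sin(2 * np.pi * freq * t[sl])
    return 2.0 * float(np.hypot((x[sl] * c).mean(), (x[sl] * s).mean()))


@pytest.fixture(scope="session")
def tiny_study():
    """2 subjects × 3 conditions, 10 s blocks — shared across io/pipeline tests."""
    cfg = SimConfig(n_subjects=2, duration_s=10.0, master_seed=3)
    study, truth = simulate_study(cfg)
    return cfg, study, truth
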