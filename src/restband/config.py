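"""Flat text configuration for the analysis pipeline.

One YAML file drives every stage; there are no hidden defaults outside
:data:`DEFAULT_CONFIG`. Keys are grouped in flat sections::

    filter:   band_low, band_high, order, notch_freq, notch_bw
    epoch:    length_ms, overlap_ms
    reject:   threshold_uv, scope, criterion
    spectral: window, band_aggregate
    bands:    {name: {low, high}}
    channels: [Fz, Cz, Pz]
    conditions: [...]          # conditions entering the statistics
    stats:    ci_level, pairwise_error_term

:func:`validate_config` reports unknown keys (with nearest-match
suggestions), out-of-range values and Nyquist violations without side
effects.
"""

from __future__ import annotations

import copy
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .preprocess import FilterSpec
from .spectral import BandDefinition

__all__ = [
    "DEFAULT_CONFIG",
    "PipelineConfig",
    "load_config",
    "validate_config",
]

DEFAULT_CONFIG: dict[str, Any] = {
    "filter": {
        "band_low": 0.1,
        "band_high": 30.0,
        "order": 2,
        "notch_freq": 60.0,
        "notch_bw": 2.0,
    },
    "epoch": {"length_ms": 1000.0, "overlap_ms": 500.0},
    "reject": {"threshold_uv": 150.0, "scope": "channel", "criterion": "peak_to_peak"},
    "spectral": {"window": "rect", "band_aggregate": "mean"},
    "bands": {
        "theta": {"low": 4.0, "high": 7.0},
        "alpha": {"low": 8.0, "high": 12.0},
        "beta": {"low": 13.0, "high": 30.0},
    },
    "channels": ["Fz", "Cz", "Pz"],
    "conditions": ["no_glasses", "clear_glasses", "filter_glasses"],
    "stats": {"ci_level": 0.95, "pairwise_error_term": "anova_pooled"},
}

_ALLOWED = {
    "filter": {"band_low", "band_high", "order", "notch_freq", "notch_bw"},
    "epoch": {"length_ms", "overlap_ms"},
    "reject": {"threshold_uv", "scope", "criterion"},
    "spectral": {"window", "band_aggregate"},
    "stats": {"ci_level", "pairwise_error_term"},
}
_TOP_KEYS = set(DEFAULT_CONFIG)


def _merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in base.items():
        if isinstance(v, Mapping) and isinstance(override.get(k), Mapping):
            out[k] = _merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k, v in override.items():
        out.setdefault(k, v)
    return out


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (defaults merged with a user file)."""

    raw: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @property
    def filter_spec(self) -> FilterSpec:
        f = self.raw["filter"]
        return FilterSpec(
            band_low=float(f["band_low"]),
            band_high=float(f["band_high"]),
            order_per_pass=int(f["order"]),
            notch_freq=float(f["notch_freq"]),
            notch_bandwidth=float(f["notch_bw"]),
        )

    @property
    def bands(self) -> list[BandDefinition]:
        return [
            BandDefinition(name, float(b["low"]), float(b["high"]))
            for name, b in self.raw["bands"].items()
        ]

    @property
    def channels(self) -> list[str]:
        return list(self.raw["channels"])

    @property
    def conditions(self) -> list[str]:
        return list(self.raw["conditions"])

    @property
    def epoch_length_ms(self) -> float:
        return float(self.raw["epoch"]["length_ms"])

    @property
    def overlap_ms(self) -> float:
        return float(self.raw["epoch"]["overlap_ms"])

    @property
    def reject_threshold_uv(self) -> float:
        return float(self.raw["reject"]["threshold_uv"])

    @property
    def reject_scope(self) -> str:
        return str(self.raw["reject"]["scope"])

    @property
    def window(self) -> str:
        return str(self.raw["spectral"]["window"])

    @property
    def band_aggregate(self) -> str:
        return str(self.raw["spectral"]["band_aggregate"])

    @property
    def ci_level(self) -> float:
        return float(self.raw["stats"]["ci_level"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=False)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config merged over the shipped defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config {path} must be a mapping, got {type(user).__name__}")
    return PipelineConfig(_merge(DEFAULT_CONFIG, user))


def _suggest(key: str, pool: set[str]) -> str:
    match = difflib.get_close_matches(key, pool, n=1)
    return f" (did you mean {match[0]!r}?)" if match else ""


def validate_config(
    path: str | Path | None = None,
    sampling_rate: float = 1000.0,
    config: PipelineConfig | None = None,
) -> list[str]:
    """Diagnostics for a config file: unknown keys, ranges, Nyquist checks.

    Returns a list of human-readable problem descriptions (empty when the
    configuration is clean). No side effects.
    """
    diags: list[str] = []
    if config is None:
        try:
            user = yaml.safe_load(Path(path).read_text()) if path is not None else {}
        except yaml.YAMLError as exc:
            return [f"could not parse config: {exc}"]
        user = user or {}
        if not isinstance(user, Mapping):
            return ["config must be a top-level mapping"]
        for k in user:
            if k not in _TOP_KEYS:
                diags.append(f"unknown section {k!r}{_suggest(k, _TOP_KEYS)}")
        for section, allowed in _ALLOWED.items():
            sub = user.get(section)
            if isinstance(sub, Mapping):
                for k in sub:
                    if k not in allowed:
                        diags.append(
                            f"unknown key {section}.{k}{_suggest(k, allowed)}"
                        )
        config = PipelineConfig(_merge(DEFAULT_CONFIG, user))

    nyq = sampling_rate / 2.0
    f = config.raw["filter"]
    if not 0 < float(f["band_low"]) < float(f["band_high"]):
        diags.append(f"filter: need 0 < band_low < band_high, got {f['band_low']}, {f['band_high']}")
    if float(f["band_high"]) >= nyq:
        diags.append(f"filter.band_high {f['band_high']} Hz >= Nyquist ({nyq} Hz)")
    if float(f["notch_freq"]) >= nyq:
        diags.append(f"filter.notch_freq {f['notch_freq']} Hz >= Nyquist ({nyq} Hz)")
    if int(f["order"]) < 1:
        diags.append("filter.order must be >= 1")
    e = config.raw["epoch"]
    if not 0 <= float(e["overlap_ms"]) < float(e["length_ms"]):
        diags.append(f"epoch: need 0 <= overlap_ms < length_ms, got {e['overlap_ms']}, {e['length_ms']}")
    r = config.raw["reject"]
    if float(r["threshold_uv"]) <= 0:
        diags.append("reject.threshold_uv must be > 0")
    if r["scope"] not in ("channel", "epoch"):
        diags.append(f"reject.scope must be 'channel' or 'epoch', got {r['scope']!r}")
    if r["criterion"] not in ("peak_to_peak", "successive_difference"):
        diags.append(f"unknown reject.criterion {r['criterion']!r}")
    s = config.raw["spectral"]
    if s["window"] not in ("rect", "hann"):
        diags.append(f"spectral.window must be 'rect' or 'hann', got {s['window']!r}")
    if s["band_aggregate"] not in ("mean", "sum"):
        diags.append(f"spectral.band_aggregate must be 'mean' or 'sum', got {s['band_aggregate']!r}")
    for name, b in config.raw["bands"].items():
        if float(b["low"]) > float(b["high"]):
            diags.append(f"band {name}: low > high")
        if float(b["high"]) > nyq:
            diags.append(f"band {name}: high {b['high']} Hz above Nyquist ({nyq} Hz)")
    st = config.raw["stats"]
    if not 0 < float(st["ci_level"]) < 1:
        diags.append(f"stats.ci_level must be in (0, 1), got {st['ci_level']}")
    if st["pairwise_error_term"] not in ("anova_pooled", "per_pair"):
        diags.append(f"unknown stats.pairwise_error_term {st['pairwise_error_term']!r}")
    return diags
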