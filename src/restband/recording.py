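"""Core containers for multichannel scalp EEG recordings.

A :class:`Recording` is one subject-by-condition block of continuous EEG:
a channels × samples array of potentials in microvolts, with 10–20 channel
labels and a sampling rate. A :class:`StudyDataset` collects recordings
keyed by ``(subject_id, condition)`` for a repeated-measures study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "CONDITIONS",
    "Recording",
    "StudyDataset",
    "normalize_label",
]

#: Canonical condition labels of a light-filtering glasses study:
#: eyes-open resting state without glasses, with clear control glasses,
#: with light-filtering glasses, and an eyes-closed block.
CONDITIONS = ("no_glasses", "clear_glasses", "filter_glasses", "eyes_closed")


def normalize_label(label: str) -> str:
    """Normalize a channel label for matching: strip whitespace, casefold.

    Vendor headers disagree on case ("FZ" vs "Fz"); matching is therefore
    case-insensitive with surrounding whitespace removed.
    """
    return label.strip().casefold()


@dataclass
class Recording:
    """One continuous multichannel EEG block in microvolts.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    condition : str
        Condition label (free string; see :data:`CONDITIONS` for the
        canonical set).
    sampling_rate : float
        Samples per second (Hz); must be positive.
    channel_labels : list of str
        Ordered 10–20 channel names, unique after normalization.
    samples : ndarray, shape (n_channels, n_samples)
        Potentials in μV.
    """

    subject_id: str
    condition: str
    sampling_rate: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels × time) array")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} sample rows"
            )
        norm = [normalize_label(c) for c in self.channel_labels]
        if len(set(norm)) != len(norm):
            dupes = sorted({c for c in norm if norm.count(c) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        """Index of a channel by case-insensitive label match."""
        want = normalize_label(label)
        for i, c in enumerate(self.channel_labels):
            if normalize_label(c) == want:
                return i
        raise KeyError(f"channel {label!r} not in {self.channel_labels}")

    def get_channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def has_channels(self, labels: Iterable[str]) -> bool:
        have = {normalize_label(c) for c in self.channel_labels}
        return all(normalize_label(l) in have for l in labels)

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """New Recording with the same metadata and replaced samples."""
        return Recording(
            subject_id=self.subject_id,
            condition=self.condition,
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            samples=np.asarray(samples, dtype=float),
        )


@dataclass
class StudyDataset:
    """Recordings of a repeated-measures study keyed by (subject, condition)."""

    recordings: dict[tuple[str, str], Recording] = field(default_factory=dict)
    metadata: dict[str, Mapping[str, object]] = field(default_factory=dict)

    def add(self, rec: Recording) -> None:
        key = (rec.subject_id, rec.condition)
        if key in self.recordings:
            raise ValueError(f"duplicate recording for {key}")
        self.recordings[key] = rec

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[Recording]:
        return iter(self.recordings.values())

    def get(self, subject_id: str, condition: str) -> Recording:
        return self.recordings[(subject_id, condition)]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.recordings:
            seen.setdefault(sid)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cond in self.recordings:
            seen.setdefault(cond)
        return list(seen)

    def conditions_of(self, subject_id: str) -> list[str]:
        return [c for (s, c) in self.recordings if s == subject_id]

    def complete_subjects(self, conditions: Iterable[str]) -> list[str]:
        """Subjects that have every condition in ``conditions``."""
        wanted = list(conditions)
        return [
            s
            for s in self.subjects
            if all((s, c) in self.recordings for c in wanted)
        ]

    def incomplete_subjects(self, conditions: Iterable[str]) -> list[str]:
        wanted = list(conditions)
        complete = set(self.complete_subjects(wanted))
        return [s for s in self.subjects if s not in complete]
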