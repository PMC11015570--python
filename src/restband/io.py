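"""Reading and writing study data: EDF/CSV recordings, manifests, tables.

EDF ingestion goes through :func:`mne.io.read_raw_edf` with unit conversion
to μV (MNE honours the header's physical dimension, so mV/V declarations
are converted). Delimited-text recordings are a header row of channel
labels over one column per channel, with an optional leading time/index
column; the sampling rate for text files is never inferred from timestamps
and must be given explicitly.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording, StudyDataset, normalize_label
from .spectral import BandPowerTable

__all__ = [
    "read_recording",
    "read_recording_csv",
    "read_recording_edf",
    "write_recording_csv",
    "load_study",
    "write_band_power_table",
    "read_band_power_table",
    "write_report",
]

logger = logging.getLogger(__name__)

#: Header names recognized as a leading time/sample-index column (normalized).
_TIME_COLUMNS = {"time", "time_s", "time_ms", "t", "sample", "index", "n"}


def read_recording(
    path: str | Path,
    format: str,
    subject_id: str,
    condition: str,
    sampling_rate: float | None = None,
) -> Recording:
    """Read one recording from EDF or delimited text.

    For ``format="csv"`` an explicit ``sampling_rate`` is required; for
    ``format="edf"`` the rate comes from the file header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if format == "edf":
        return read_recording_edf(path, subject_id, condition)
    if format == "csv":
        if sampling_rate is None:
            raise ValueError(
                f"sampling rate must be given explicitly for delimited text ({path}); "
                "it is never inferred from timestamps"
            )
        return read_recording_csv(path, subject_id, condition, sampling_rate)
    raise ValueError(f"unknown recording format {format!r} (expected 'edf' or 'csv')")


def read_recording_edf(path: str | Path, subject_id: str, condition: str) -> Recording:
    """Read an EDF file via MNE; samples returned in μV."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface reader failures with the path
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ValueError(f"EDF file {path} contains no channels")
    data = raw.get_data(units="uV")
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        samples=data,
    )


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_recording_csv(
    path: str | Path, subject_id: str, condition: str, sampling_rate: float
) -> Recording:
    """Read a delimited-text recording (header of channel labels, μV values)."""
    path = Path(path)
    with open(path, "r", newline="") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"empty recording file: {path}")
    delim = _sniff_delimiter(header_line)
    header = next(csv.reader([header_line], delimiter=delim))
    header = [h.strip() for h in header]
    drop_first = bool(header) and normalize_label(header[0]) in _TIME_COLUMNS
    channels = header[1:] if drop_first else header
    if not channels:
        raise ValueError(f"no channel columns in {path}")
    norm = [normalize_label(c) for c in channels]
    if len(set(norm)) != len(norm):
        dupes = sorted({c for c in norm if norm.count(c) > 1})
        raise ValueError(f"duplicate channel labels in {path}: {dupes}")
    try:
        frame = pd.read_csv(path, sep=delim, header=0, dtype=float, skip_blank_lines=True)
    except ValueError as exc:
        raise ValueError(f"could not parse recording {path}: {exc}") from exc
    if drop_first:
        frame = frame.iloc[:, 1:]
    if frame.empty:
        raise ValueError(f"recording {path} has a header but no samples")
    return Recording(
        subject_id=subject_id,
        condition=condition,
        sampling_rate=sampling_rate,
        channel_labels=channels,
        samples=frame.to_numpy(dtype=float).T,
    )


def write_recording_csv(rec: Recording, path: str | Path, precision: int = 6) -> Path:
    """Write a recording as comma-separated text (header of channel labels)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.samples.T, fmt=f"%.{precision}f", delimiter=",")
    return path


MANIFEST_COLUMNS = ("subject_id", "condition", "path", "format")


def load_study(
    manifest: str | Path, sampling_rate: float | None = None
) -> StudyDataset:
    """Load all recordings listed in a delimited manifest.

    The manifest needs columns subject_id, condition, path, format; an
    optional ``sampling_rate`` column (or the function argument) supplies
    the rate for text recordings. Relative paths resolve against the
    manifest's directory. All per-file failures are collected and reported
    together; incomplete subjects are retained but logged.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    try:
        rows = pd.read_csv(manifest, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        rows = pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing and len(rows.columns):
        raise ValueError(f"manifest {manifest} missing columns {missing}")
    study = StudyDataset()
    if rows.empty:
        logger.warning("manifest %s lists no recordings", manifest)
        return study
    dup = rows.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        bad = rows.loc[dup, ["subject_id", "condition"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, condition) manifest rows: {list(bad)}")
    failures: list[str] = []
    for _, row in rows.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = manifest.parent / p
        rate = sampling_rate
        if "sampling_rate" in rows.columns and pd.notna(row.get("sampling_rate")):
            rate = float(row["sampling_rate"])
        try:
            rec = read_recording(
                p,
                str(row["format"]).strip().lower(),
                str(row["subject_id"]),
                str(row["condition"]),
                sampling_rate=rate,
            )
            study.add(rec)
        except Exception as exc:  # noqa: BLE001 - aggregate and re-raise below
            failures.append(f"{row['subject_id']}/{row['condition']} ({p}): {exc}")
    if failures:
        raise OSError(
            "failed to load {} recording(s):\n  {}".format(len(failures), "\n  ".join(failures))
        )
    for s in study.incomplete_subjects(study.conditions):
        logger.warning(
            "subject %s incomplete: has conditions %s of %s",
            s,
            study.conditions_of(s),
            study.conditions,
        )
    return study


def write_band_power_table(table: BandPowerTable, path: str | Path) -> Path:
    """Write a band-power table as comma-separated text in canonical order.

    Power values are written with 17 significant digits so that reading the
    file back reproduces them bit-exactly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty band-power table")
    path = Path(path)
    table.sorted().data.to_csv(path, index=False, float_format="%.17g")
    return path


def read_band_power_table(path: str | Path) -> BandPowerTable:
    """Read a band-power table written by :func:`write_band_power_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"band-power table not found: {path}")
    frame = pd.read_csv(
        path, dtype={"subject_id": str, "condition": str}, float_precision="round_trip"
    )
    return BandPowerTable(frame)


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize a statistics report as structured text (JSON)."""
    from .stats import report_to_json

    path = Path(path)
    path.write_text(report_to_json(report) + "\n")
    return path
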