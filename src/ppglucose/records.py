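"""PPG record container and the plain-CSV interchange formats.

A :class:`PPGRecord` is one sampled photoplethysmogram trace: a 15 s
single-channel amplitude series with its sampling rate, the acquisition
state (fasting or postprandial) and the paired reference capillary
glucose reading in mg/dL.  Synthetic records additionally carry the
planted ground truth (beat onsets, systolic peak and dicrotic notch
sample indices) used by the test-bench.

On disk a record is a UTF-8 CSV with ``#``-prefixed header comment lines
carrying the metadata (``fs_hz``, ``subject_id``, ``state``,
``glucose_mgdl``, ``provenance``) followed by ``t_s,amplitude`` rows.
A ``sample,amplitude`` dialect (integer sample index instead of time) is
accepted on read; the sampling rate always comes from the header.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATES = ("fasting", "postprandial")


class RecordFormatError(ValueError):
    """Raised when a record CSV cannot be parsed."""


@dataclass
class GroundTruth:
    """Planted fiducials of a synthetic record (sample indices, 0-based)."""

    beat_onsets: np.ndarray
    systolic_peaks: np.ndarray
    notches: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_onsets", "systolic_peaks", "notches"):
            arr = np.asarray(getattr(self, name), dtype=int)
            setattr(self, name, arr)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"ground-truth {name} must be strictly increasing")


@dataclass
class PPGRecord:
    """One sampled PPG waveform with metadata.

    Parameters
    ----------
    samples : array of amplitude values (arbitrary units).
    fs_hz : sampling rate in Hz (~127 Hz for the target acquisition setup).
    subject_id : opaque subject identifier.
    state : ``"fasting"`` or ``"postprandial"``.
    glucose_mgdl : paired reference glucose in mg/dL.
    ground_truth : planted fiducials, present only for synthetic records.
    provenance : ordered names of processing operations already applied.
    extras : auxiliary signals (e.g. the detrended trace kept alongside a
        band-passed one so derivative morphology is not lost).
    """

    samples: np.ndarray
    fs_hz: float
    subject_id: str = "anon"
    state: str = "fasting"
    glucose_mgdl: float | None = None
    ground_truth: GroundTruth | None = None
    provenance: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.state not in VALID_STATES:
            raise ValueError(f"state must be one of {VALID_STATES}, got {self.state!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def replace(self, **changes) -> "PPGRecord":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def record_id(self) -> str:
        return f"{self.subject_id}_{self.state}"


def write_record_csv(record: PPGRecord, path: str) -> None:
    """Write a record in the ``t_s,amplitude`` CSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={float(record.fs_hz)!r}\n")
        fh.write(f"# subject_id={record.subject_id}\n")
        fh.write(f"# state={record.state}\n")
        if record.glucose_mgdl is not None:
            fh.write(f"# glucose_mgdl={float(record.glucose_mgdl)!r}\n")
        if record.provenance:
            fh.write(f"# provenance={','.join(record.provenance)}\n")
        fh.write("t_s,amplitude\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i / record.fs_hz:.9f},{float(v)!r}\n")


def read_record_csv(path: str) -> PPGRecord:
    """Read a record CSV (either the time or the sample-index dialect)."""
    meta: dict[str, str] = {}
    rows: list[float] = []
    times: list[float] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            if header is None:
                header = [p.strip().lower() for p in parts]
                if len(header) != 2 or header[1] != "amplitude" or header[0] not in ("t_s", "sample"):
                    raise RecordFormatError(
                        f"{path}: expected 't_s,amplitude' or 'sample,amplitude' header, got {line!r}"
                    )
                continue
            try:
                t, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise RecordFormatError(f"{path}: non-numeric value on line {lineno}: {line!r}") from exc
            times.append(t)
            rows.append(v)
    if header is None or not rows:
        raise RecordFormatError(f"{path}: no data rows")
    if "fs_hz" not in meta:
        raise RecordFormatError(f"{path}: missing required 'fs_hz' header metadata")
    if np.any(np.diff(times) <= 0):
        raise RecordFormatError(f"{path}: non-monotonic {header[0]} column")
    glucose = float(meta["glucose_mgdl"]) if "glucose_mgdl" in meta else None
    provenance = [p for p in meta.get("provenance", "").split(",") if p]
    return PPGRecord(
        samples=np.array(rows),
        fs_hz=float(meta["fs_hz"]),
        subject_id=meta.get("subject_id", "anon"),
        state=meta.get("state", "fasting"),
        glucose_mgdl=glucose,
        provenance=provenance,
    )


def write_cohort(records: list[PPGRecord], out_dir: str) -> pd.DataFrame:
    """Write every record plus a ``manifest.csv`` cohort manifest.

    Returns the manifest table (``subject_id, state, glucose_mgdl, record_path``).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.record_id()}.csv"
        write_record_csv(rec, os.path.join(out_dir, fname))
        rows.append(
            {
                "subject_id": rec.subject_id,
                "state": rec.state,
                "glucose_mgdl": rec.glucose_mgdl,
                "record_path": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def read_cohort(in_dir: str) -> list[PPGRecord]:
    """Read every record listed in ``manifest.csv`` under ``in_dir``."""
    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    return [read_record_csv(os.path.join(in_dir, p)) for p in manifest["record_path"]]
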