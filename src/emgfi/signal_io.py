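"""Persistence: EDF epochs, JSON session manifests, CSV feature cohorts.

On-disk layout
--------------
* One EDF file per (ring, state, repetition) epoch.  Channel labels are
  ``R<ring>E<electrode>`` (e.g. ``R2E07``), physical dimension mV, one 1-s
  data record per second.  Writing uses a minimal EDF encoder; reading goes
  through :func:`mne.io.read_raw_edf`.
* A JSON *session manifest* binds the 12 epoch files of one subject.
* Cohort feature tables are UTF-8 CSV with '.' decimal, one row per subject,
  the 12 canonical feature columns plus metadata columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CLASSES,
    FEATURE_NAMES,
    N_ELECTRODES,
    SAMPLE_RATE_HZ,
    UNKNOWN_LABEL,
    FormatError,
    Recording,
    ValidationError,
)

_EDF_DIG_MIN = -32768
_EDF_DIG_MAX = 32767

#: Metadata columns recognised in cohort CSV files, besides the 12 features.
COHORT_META_COLUMNS = ("subject_id", "label", "age", "sex", "fisi_score")


def channel_labels(ring: int) -> list[str]:
    return [f"R{ring}E{e:02d}" for e in range(1, N_ELECTRODES + 1)]


def _ascii_field(value: str, width: int) -> bytes:
    raw = value.encode("ascii")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def _format_physical(peak: float) -> str:
    """Encode a symmetric physical bound >= ``peak`` in <= 7 ASCII characters.

    Seven characters leave room for the minus sign of the negative bound, and
    rounding is always upward so no sample is clipped.
    """
    for safety in (1.0005, 1.005, 1.05, 1.5):
        for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
            s = fmt % (peak * safety)
            if len(s) <= 7 and float(s) >= peak:
                return s
    raise FormatError(f"cannot encode physical bound {peak!r} in 7 characters")


def _write_edf(
    path: str | Path,
    data: np.ndarray,
    labels: Sequence[str],
    sample_rate_hz: int,
    subject_id: str = "unknown",
    recording_id: str = "Startdate 01-JAN-2020 X X X",
) -> None:
    """Low-level EDF encoder: one int16 signal per row, physical unit mV.

    The physical range is set per file to the data extremes, so quantization
    error is at most half of ``(phys_max - phys_min) / 65535``.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValidationError("samples contain non-finite values")
    n_sig = data.shape[0]
    record_duration = 1.0
    spr = int(sample_rate_hz * record_duration)
    n_records = data.shape[1] // spr
    if n_records * spr != data.shape[1]:
        raise ValidationError("epoch length must be a whole number of seconds")

    peak = float(np.max(np.abs(data)))
    # Round-trip the ASCII encoding so writer and reader use identical bounds.
    phys_max_s = _format_physical(max(peak, 1e-6))
    phys_min_s = "-" + phys_max_s
    phys_max = float(phys_max_s)
    phys_min = float(phys_min_s)

    header = b""
    header += _ascii_field("0", 8)
    header += _ascii_field(f"{subject_id} X X X", 80)
    header += _ascii_field(recording_id, 80)
    header += _ascii_field("01.01.20", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(str(256 * (1 + n_sig)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_records), 8)
    header += _ascii_field(str(record_duration), 8)
    header += _ascii_field(str(n_sig), 4)
    header += b"".join(_ascii_field(lab, 16) for lab in labels)
    header += _ascii_field("AgBar", 80) * n_sig
    header += _ascii_field("mV", 8) * n_sig
    header += _ascii_field(phys_min_s, 8) * n_sig
    header += _ascii_field(phys_max_s, 8) * n_sig
    header += _ascii_field(str(_EDF_DIG_MIN), 8) * n_sig
    header += _ascii_field(str(_EDF_DIG_MAX), 8) * n_sig
    header += _ascii_field("BP:10-500Hz", 80) * n_sig
    header += _ascii_field(str(spr), 8) * n_sig
    header += _ascii_field("", 32) * n_sig

    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.clip(
        np.round((data - phys_min) / scale) + _EDF_DIG_MIN, _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write one epoch as an EDF file (16 signals, channel labels R<ring>E<nn>)."""
    recording.validate()
    rec_id = (
        f"Startdate 01-JAN-2020 subject_{recording.subject_id}"
        f" ring_{recording.ring} state_{recording.state} rep_{recording.repetition}"
    )
    _write_edf(
        path,
        recording.samples,
        channel_labels(recording.ring),
        recording.sample_rate_hz,
        subject_id=recording.subject_id,
        recording_id=rec_id,
    )


def read_recording(path: str | Path, ring: int, state: str, repetition: int) -> Recording:
    """Read one epoch from EDF.  Channel labels must match ``R<ring>E01..16``."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    expected = channel_labels(ring)
    got = list(raw.ch_names)
    if got != expected:
        missing = sorted(set(expected) - set(got))
        extra = sorted(set(got) - set(expected))
        raise FormatError(
            f"channel labels do not match ring {ring}: missing {missing}, unexpected {extra}"
        )
    if int(round(raw.info["sfreq"])) != SAMPLE_RATE_HZ:
        raise FormatError(
            f"sample rate {raw.info['sfreq']} Hz does not match required {SAMPLE_RATE_HZ} Hz;"
            " resampling is not supported"
        )
    data_v = raw.get_data()  # mne rescales mV-dimension channels to volts
    subject_id = _subject_from_edf(path)
    return Recording(
        subject_id=subject_id,
        ring=ring,
        state=state,
        repetition=repetition,
        samples=data_v * 1e3,
        duration_s=data_v.shape[1] / SAMPLE_RATE_HZ,
    )


def _subject_from_edf(path: Path) -> str:
    with open(path, "rb") as fh:
        header = fh.read(256)
    patient = header[8:88].decode("ascii", errors="replace").strip()
    return patient.split(" ")[0] if patient else "unknown"


def write_session(
    recordings: Iterable[Recording], directory: str | Path, subject_id: str | None = None
) -> Path:
    """Write a complete 12-epoch session plus its JSON manifest.

    Returns the manifest path.  File names encode the epoch coordinates:
    ``<subject>_r<ring><state><rep>.edf``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recordings = list(recordings)
    if subject_id is None:
        subject_id = recordings[0].subject_id
    keys = sorted(r.key() for r in recordings)
    expected = sorted((ring, state, rep) for ring in (1, 2, 3) for state in ("R", "C") for rep in (1, 2))
    if keys != expected:
        raise ValidationError(f"session must contain exactly the 12 epochs, got {keys}")
    entries = []
    for rec in recordings:
        fname = f"{subject_id}_r{rec.ring}{rec.state}{rec.repetition}.edf"
        write_recording(rec, directory / fname)
        entries.append(
            {"file": fname, "ring": rec.ring, "state": rec.state, "repetition": rec.repetition}
        )
    manifest = {
        "schema": "emgfi-session/1",
        "subject_id": subject_id,
        "sample_rate_hz": SAMPLE_RATE_HZ,
        "epochs": sorted(entries, key=lambda e: (e["ring"], e["state"], e["repetition"])),
    }
    manifest_path = directory / f"{subject_id}_session.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_session(manifest_path: str | Path) -> list[Recording]:
    """Load the 12 epochs referenced by a session manifest."""
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed session manifest {manifest_path}: {exc}") from exc
    if manifest.get("schema") != "emgfi-session/1":
        raise FormatError(f"unrecognised manifest schema in {manifest_path}")
    epochs = manifest.get("epochs", [])
    if len(epochs) != 12:
        raise FormatError(f"manifest lists {len(epochs)} epochs, expected 12")
    recordings = []
    for entry in epochs:
        rec = read_recording(
            manifest_path.parent / entry["file"],
            ring=entry["ring"],
            state=entry["state"],
            repetition=entry["repetition"],
        )
        rec.subject_id = manifest["subject_id"]
        recordings.append(rec)
    return recordings


def write_cohort(table: pd.DataFrame, path: str | Path, decimals: int = 10) -> None:
    """Write a cohort feature table to CSV (lossless at ``decimals`` places)."""
    validate_cohort(table)
    cols = [c for c in COHORT_META_COLUMNS if c in table.columns] + list(FEATURE_NAMES)
    table[cols].to_csv(path, index=False, float_format=f"%.{decimals}g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, checking the canonical 12-feature header."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise FormatError(f"cohort file is missing canonical feature columns: {missing}")
    validate_cohort(table)
    return table


def validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table is missing canonical feature columns: {missing}")
    if "label" in table.columns:
        bad = sorted(set(table["label"].astype(str)) - set(CLASSES) - {UNKNOWN_LABEL})
        if bad:
            raise ValidationError(f"labels outside the class set: {bad}")
    if "subject_id" in table.columns and table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids: {dupes}")


def cohort_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
    """Return (X, y) arrays in canonical feature/class order; y is None if unlabeled."""
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = None
    if "label" in table.columns:
        labels = table["label"].astype(str).to_numpy()
        if not (labels == UNKNOWN_LABEL).all():
            y = labels
    return X, y
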