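"""Reading and writing ECG records and tabular artifacts.

Two on-disk record formats are supported:

* **csv** — one file per record with a single ``amplitude_mv`` column,
  plus a ``metadata.csv`` sidecar in the same directory
  (record_id, fs, age, sex, site_id) shared by all records of a cohort.
* **wfdb** — a minimal single-channel WFDB pair (``.hea`` header +
  16-bit little-endian ``.dat``), with age/sex/site carried as header
  comment lines. Amplitudes are quantized to the header's ADC gain
  (default 4096 adu/mV), so a write→read round trip is exact only up to
  half a quantization step unless the input already sits on the grid.

Sample indices are 0-based and times are seconds from record start
throughout the package. Sex is encoded male→0, female→1 in numeric
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidParameterError

logger = logging.getLogger(__name__)

SEX_CODES = {"male": 0, "female": 1}
WFDB_GAIN = 4096  # adu per mV; 16-bit range then covers ±8 mV


@dataclass
class ECGRecord:
    """A single-lead ECG trace with subject metadata."""

    record_id: str
    signal: np.ndarray
    fs: float
    age: float
    sex: str
    site_id: str = "site_0"
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.signal.size == 0:
            raise InvalidParameterError("signal must be non-empty")
        if not np.isnan(self.age) and self.age < 0:
            raise InvalidParameterError(f"age must be non-negative, got {self.age}")
        if np.isnan(self.age) or self.sex not in SEX_CODES:
            # missing demographics: keep the record but mark it for exclusion
            self.flagged = True
            logger.warning(
                "record %s: missing/unknown age or sex; flagged for exclusion",
                self.record_id,
            )

    @property
    def sex_code(self) -> int:
        return SEX_CODES.get(self.sex, -1)

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


# --------------------------------------------------------------------------
# CSV format
# --------------------------------------------------------------------------

def _metadata_path(record_path: Path) -> Path:
    return record_path.parent / "metadata.csv"


def write_record_csv(record: ECGRecord, directory: str | Path) -> Path:
    """Write ``<record_id>.csv`` and upsert the cohort ``metadata.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{record.record_id}.csv"
    # %.17g round-trips float64 exactly through text
    pd.DataFrame({"amplitude_mv": record.signal}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta_path = _metadata_path(path)
    row = pd.DataFrame(
        [{"record_id": record.record_id, "fs": record.fs, "age": record.age,
          "sex": record.sex, "site_id": record.site_id}]
    )
    if meta_path.exists():
        meta = pd.read_csv(meta_path)
        meta = meta[meta["record_id"] != record.record_id]
        meta = pd.concat([meta, row], ignore_index=True)
    else:
        meta = row
    meta.to_csv(meta_path, index=False)
    return path


def _read_record_csv(path: Path) -> ECGRecord:
    record_id = path.stem
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    if "amplitude_mv" not in frame.columns:
        raise FormatError(f"{path}: missing required column 'amplitude_mv'")
    values = pd.to_numeric(frame["amplitude_mv"], errors="coerce")
    bad = np.nonzero(values.isna().to_numpy())[0]
    if bad.size:
        # +2: one for the header line, one for 1-based line numbering
        raise FormatError(
            f"{path}: non-numeric sample in column 'amplitude_mv' at line {bad[0] + 2}"
        )
    meta_path = _metadata_path(path)
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = pd.read_csv(meta_path)
    hit = meta[meta["record_id"].astype(str) == record_id]
    if hit.empty:
        raise FormatError(f"{meta_path}: no metadata row for record_id {record_id!r}")
    row = hit.iloc[0]
    age = float(row["age"]) if pd.notna(row["age"]) else float("nan")
    sex = str(row["sex"]) if pd.notna(row["sex"]) else "unknown"
    return ECGRecord(
        record_id=record_id,
        signal=values.to_numpy(dtype=float),
        fs=float(row["fs"]),
        age=age,
        sex=sex,
        site_id=str(row["site_id"]),
    )


# --------------------------------------------------------------------------
# Minimal WFDB (format 16, one channel)
# --------------------------------------------------------------------------

def write_record_wfdb(record: ECGRecord, directory: str | Path,
                      gain: int = WFDB_GAIN) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.signal * gain)
    if np.any(np.abs(adc) > 32767):
        raise InvalidParameterError(
            f"record {record.record_id}: amplitude exceeds ±{32767 / gain:.3f} mV "
            f"representable at gain {gain}"
        )
    adc = adc.astype("<i2")
    dat_name = f"{record.record_id}.dat"
    header = directory / f"{record.record_id}.hea"
    n = adc.size
    first = int(adc[0])
    checksum = int(np.sum(adc.astype(np.int64)) % 65536)
    lines = [
        f"{record.record_id} 1 {record.fs:g} {n}",
        f"{dat_name} 16 {gain}/mV 16 0 {first} {checksum} 0 ECG",
        f"# age: {record.age:g}",
        f"# sex: {record.sex}",
        f"# site: {record.site_id}",
    ]
    header.write_text("\n".join(lines) + "\n")
    (directory / dat_name).write_bytes(adc.tobytes())
    return header


def _read_record_wfdb(path: Path) -> ECGRecord:
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise FormatError(f"{header}: WFDB header not found")
    lines = [ln.strip() for ln in header.read_text().splitlines() if ln.strip()]
    try:
        rec_fields = lines[0].split()
        record_id, _n_sig, fs, n_samples = (
            rec_fields[0], int(rec_fields[1]), float(rec_fields[2]), int(rec_fields[3])
        )
        sig_fields = lines[1].split()
        dat_name, fmt, gain_spec = sig_fields[0], sig_fields[1], sig_fields[2]
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{header}: malformed WFDB header line ({exc})") from exc
    if fmt != "16":
        raise FormatError(f"{header}: unsupported WFDB sample format {fmt!r} (only 16)")
    gain = float(gain_spec.split("/")[0])
    meta = {"age": float("nan"), "sex": "unknown", "site": "site_0"}
    for ln in lines[2:]:
        if ln.startswith("#") and ":" in ln:
            key, _, value = ln.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    dat = header.parent / dat_name
    if not dat.exists():
        raise FormatError(f"{dat}: WFDB signal file not found")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if raw.size != n_samples:
        raise FormatError(
            f"{dat}: expected {n_samples} samples per header, found {raw.size}"
        )
    return ECGRecord(
        record_id=record_id,
        signal=raw.astype(float) / gain,
        fs=fs,
        age=float(meta["age"]),
        sex=str(meta["sex"]),
        site_id=str(meta["site"]),
    )


# --------------------------------------------------------------------------
# Public record API
# --------------------------------------------------------------------------

def write_record(record: ECGRecord, directory: str | Path,
                 format: str = "csv") -> Path:
    if format == "csv":
        return write_record_csv(record, directory)
    if format == "wfdb":
        return write_record_wfdb(record, directory)
    raise FormatError(f"unknown record format {format!r} (expected 'csv' or 'wfdb')")


def read_record(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read one ECG record; metadata comes from the sidecar/header."""
    path = Path(path)
    if not path.exists() and format == "wfdb" and path.with_suffix(".hea").exists():
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format == "csv":
        return _read_record_csv(path)
    if format == "wfdb":
        return _read_record_wfdb(path)
    raise FormatError(f"unknown record format {format!r} (expected 'csv' or 'wfdb')")


# --------------------------------------------------------------------------
# Tabular artifacts
# --------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as UTF-8 CSV with a deterministic column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    return pd.read_csv(path)


def write_ground_truth(r_times_per_record: dict[str, np.ndarray],
                       path: str | Path) -> None:
    """Ground-truth R times as long-format CSV (record_id, r_time_s)."""
    rows = [
        {"record_id": rid, "r_time_s": t}
        for rid, times in r_times_per_record.items()
        for t in np.asarray(times, float)
    ]
    pd.DataFrame(rows, columns=["record_id", "r_time_s"]).to_csv(path, index=False)
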