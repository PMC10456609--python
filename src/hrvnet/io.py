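"""Reading and writing ECG records and derived artifacts.

Two on-disk record formats are supported:

* a two-column CSV (``time_s,voltage_mV``) with a JSON sidecar carrying the
  sampling rate, subject id, class label and — for synthetic records — the
  ground-truth R-peak sample indices;
* WFDB records (``.hea`` header plus ``.dat`` signal file), formats 212
  (packed 12-bit pairs) and 16 (little-endian int16).

Sample indices are 0-based, times are in seconds, amplitudes in mV
(digital WFDB values are converted with the header gain/baseline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical rhythm-class labels
CLASS_LABELS = ("NSR", "CAD", "CHF", "VT", "SCD")

#: feature-table column order (statistics first, then the interval count)
FEATURE_COLUMNS = (
    "MRR", "SDRR", "RMSSD", "PNN50", "CVRR", "NN50", "Min_RR", "Max_RR", "N",
)


class RecordFormatError(ValueError):
    """File does not parse as a supported ECG record format."""


class HeaderParseError(RecordFormatError):
    """WFDB header line could not be interpreted."""


class TruncatedFileError(RecordFormatError):
    """Signal file holds fewer samples than the header promises."""


class MissingChannelError(ValueError):
    """Requested channel index exceeds the channel count."""


@dataclass
class EcgRecord:
    """Single-channel ECG waveform with its acquisition metadata.

    Attributes
    ----------
    samples : ndarray
        Voltage samples in mV.
    fs : float
        Sampling frequency in Hz.
    subject_id : str
        Identifier of the recording subject.
    label : str, optional
        Rhythm class, one of ``CLASS_LABELS``.
    source : str
        Originating file path, or ``"synthetic"``.
    ground_truth_peaks : ndarray, optional
        Known R-peak sample indices (synthetic records only).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    label: Optional[str] = None
    source: str = "synthetic"
    ground_truth_peaks: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.ground_truth_peaks is not None:
            p = np.asarray(self.ground_truth_peaks, dtype=np.int64)
            if p.size and (np.any(np.diff(p) <= 0) or p[0] < 0
                           or p[-1] >= self.samples.size):
                raise ValueError(
                    "ground_truth_peaks must be strictly increasing within "
                    "[0, len(samples))")
            self.ground_truth_peaks = p

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of the record with the waveform replaced."""
        return replace(self, samples=np.asarray(samples, dtype=float))


# ---------------------------------------------------------------------------
# CSV records


def write_record_csv(record: EcgRecord, path: Path | str) -> Path:
    """Write ``time_s,voltage_mV`` CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    t = np.arange(record.samples.size) / record.fs
    df = pd.DataFrame({"time_s": t, "voltage_mV": record.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": record.fs,
        "subject_id": record.subject_id,
        "label": record.label,
        "source": record.source,
        "ground_truth_peaks": (
            None if record.ground_truth_peaks is None
            else [int(i) for i in record.ground_truth_peaks]),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def _read_record_csv(path: Path, channel: int) -> EcgRecord:
    if channel != 0:
        raise MissingChannelError(
            f"CSV records are single-channel; channel {channel} requested")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise RecordFormatError(f"{path}: expected two columns (time, voltage)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise RecordFormatError(f"{path}: record too short")
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta["fs"])
        gtp = meta.get("ground_truth_peaks")
        rec = EcgRecord(
            v, fs, subject_id=meta.get("subject_id", path.stem),
            label=meta.get("label"), source=str(path),
            ground_truth_peaks=None if gtp is None else np.asarray(gtp))
    else:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise RecordFormatError(f"{path}: non-uniform time column")
        rec = EcgRecord(v, 1.0 / dt[0], subject_id=path.stem, source=str(path))
    return rec


# ---------------------------------------------------------------------------
# WFDB records (.hea + .dat, formats 212 and 16)


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str = "mV"


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise HeaderParseError(f"{hea_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise HeaderParseError(f"{hea_path}: record line needs "
                               "'name nsig fs nsamples'")
    name = head[0].split("/")[0]
    try:
        nsig = int(head[1])
        fs = float(head[2].split("/")[0])
        nsamp = int(head[3])
    except ValueError as exc:
        raise HeaderParseError(f"{hea_path}: bad record line {lines[0]!r}") from exc
    specs: list[_SignalSpec] = []
    for ln in lines[1:1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise HeaderParseError(f"{hea_path}: bad signal line {ln!r}")
        fmt_field = parts[1].split("x")[0].split(":")[0].split("+")[0]
        try:
            fmt = int(fmt_field)
        except ValueError as exc:
            raise HeaderParseError(f"{hea_path}: bad format {parts[1]!r}") from exc
        gain, baseline, units = 200.0, 0, "mV"
        if len(parts) >= 3:
            gf = parts[2]
            if "/" in gf:
                gf, units = gf.split("/", 1)
            if "(" in gf:
                gf, base = gf.rstrip(")").split("(")
                baseline = int(base)
            elif len(parts) >= 5:
                baseline = int(parts[4])  # adc_zero stands in for baseline
            gain = float(gf) or 200.0
        specs.append(_SignalSpec(parts[0], fmt, gain, baseline, units))
    if len(specs) != nsig:
        raise HeaderParseError(f"{hea_path}: {nsig} signals declared, "
                               f"{len(specs)} described")
    return name, nsig, fs, nsamp, specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    n_pairs = (n_values + 1) // 2
    if len(raw) < n_pairs * 3:
        raise TruncatedFileError(
            f"format-212 data holds {len(raw)} bytes, "
            f"{n_pairs * 3} required for {n_values} samples")
    b = np.frombuffer(raw[:n_pairs * 3], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_pairs * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def _decode_16(raw: bytes, n_values: int) -> np.ndarray:
    if len(raw) < 2 * n_values:
        raise TruncatedFileError(
            f"format-16 data holds {len(raw)} bytes, {2 * n_values} required")
    return np.frombuffer(raw[:2 * n_values], dtype="<i2")[:n_values].astype(np.int32)


def _read_record_wfdb(hea_path: Path, channel: int) -> EcgRecord:
    name, nsig, fs, nsamp, specs = _parse_header(hea_path)
    if not 0 <= channel < nsig:
        raise MissingChannelError(
            f"{hea_path}: channel {channel} requested, record has {nsig}")
    fmts = {s.fmt for s in specs}
    if len(fmts) > 1:
        raise RecordFormatError(f"{hea_path}: mixed signal formats unsupported")
    fmt = fmts.pop()
    dat_path = hea_path.parent / specs[0].file_name
    raw = dat_path.read_bytes()
    n_values = nsamp * nsig
    if fmt == 212:
        digital = _decode_212(raw, n_values)
    elif fmt == 16:
        digital = _decode_16(raw, n_values)
    else:
        raise RecordFormatError(f"{hea_path}: unsupported format {fmt}")
    spec = specs[channel]
    chan = digital.reshape(nsamp, nsig)[:, channel]
    physical = (chan - spec.baseline) / spec.gain
    logger.info("read WFDB record %s: fs=%.6g Hz, %d samples (%.1f s), "
                "channel %d/%d", name, fs, nsamp, nsamp / fs, channel, nsig)
    return EcgRecord(physical, fs, subject_id=name, source=str(hea_path))


def write_record_wfdb(record: EcgRecord, hea_path: Path | str, *,
                      fmt: int = 16, gain: float = 200.0,
                      n_channels: int = 1,
                      extra_channels: Sequence[np.ndarray] = ()) -> Path:
    """Write a WFDB record (formats 16 or 212) from one or more channels.

    ``record.samples`` is channel 0; ``extra_channels`` (same length) follow.
    Digital values are ``round(mV * gain)`` clipped to the format's range.
    """
    hea_path = Path(hea_path)
    channels = [record.samples, *[np.asarray(c, float) for c in extra_channels]]
    nsig = len(channels)
    if n_channels not in (1, nsig):
        raise ValueError("n_channels disagrees with supplied channels")
    nsamp = record.samples.size
    if any(c.size != nsamp for c in channels):
        raise ValueError("all channels must share the record length")
    lim = 2047 if fmt == 212 else 32767
    digital = np.stack([
        np.clip(np.round(c * gain), -lim - 1, lim).astype(np.int32)
        for c in channels], axis=1).reshape(-1)
    dat_name = hea_path.stem + ".dat"
    if fmt == 212:
        if digital.size % 2:
            digital = np.concatenate([digital, [0]])
        vals = digital & 0xFFF
        b = np.empty((vals.size // 2, 3), dtype=np.uint8)
        b[:, 0] = vals[0::2] & 0xFF
        b[:, 1] = ((vals[0::2] >> 8) & 0x0F) | (((vals[1::2] >> 8) & 0x0F) << 4)
        b[:, 2] = vals[1::2] & 0xFF
        payload = b.tobytes()
    elif fmt == 16:
        payload = digital.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported write format {fmt}")
    (hea_path.parent / dat_name).write_bytes(payload)
    sig_lines = "\n".join(
        f"{dat_name} {fmt} {gain:g}(0)/mV 12 0 0 0 0 ch{i}"
        for i in range(nsig))
    hea_path.write_text(
        f"{hea_path.stem} {nsig} {record.fs:g} {nsamp}\n{sig_lines}\n")
    return hea_path


def read_record(path: Path | str, channel: int = 0) -> EcgRecord:
    """Read an ECG record from CSV or WFDB, returning one channel in mV."""
    path = Path(path)
    if path.suffix == ".hea":
        return _read_record_wfdb(path, channel)
    if path.suffix == ".csv":
        rec = _read_record_csv(path, channel)
        logger.info("read CSV record %s: fs=%.6g Hz, %.1f s",
                    rec.subject_id, rec.fs, rec.duration)
        return rec
    raise RecordFormatError(f"{path}: unknown record format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(rows: Sequence[dict], path: Path | str) -> Path:
    """Write per-segment HRV features as CSV.

    Each row is a mapping holding ``subject_id``, ``segment``, ``label`` and
    the nine feature values of ``FEATURE_COLUMNS``.
    """
    if not len(rows):
        raise ValueError("feature table must have at least one row")
    path = Path(path)
    df = pd.DataFrame(list(rows))
    cols = ["subject_id", "segment", *FEATURE_COLUMNS, "label"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature rows missing columns {missing}")
    df[cols].to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: Path | str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: not a feature table, missing {missing}")
    return df
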