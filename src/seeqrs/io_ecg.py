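"""Reading and writing ECG signals and beat annotations.

Supports three plain interchange formats:

* WFDB header/signal pairs (format 16, the encoding used by the PTB
  Diagnostic ECG Database): ``read_wfdb_record``.
* Single-lead CSV text, one sample per line: ``read_csv_signal`` /
  ``write_csv_signal``.
* Beat annotations as plain text, one 0-based sample index per line with a
  ``# record lead fs`` header: ``write_detections`` / ``read_detections`` /
  ``read_annotations``.

Sample indexing is 0-based everywhere; time ``t`` maps to index
``floor(t * fs)`` and segments are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import FormatError, InputError, RangeError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .detect import QRSDetections

__all__ = [
    "ECGRecord",
    "BeatAnnotations",
    "read_wfdb_record",
    "read_csv_signal",
    "write_csv_signal",
    "select_segment",
    "write_detections",
    "read_detections",
    "read_annotations",
    "write_annotations",
]


@dataclass
class ECGRecord:
    """A multi-lead sampled ECG.

    Parameters
    ----------
    record_id : str
        Identifier of the record (WFDB record name or a caller-chosen label).
    fs : float
        Sampling frequency in Hz; must be positive.
    lead_names : list of str
        One unique label per lead, in signal order.
    samples : ndarray of shape (n_leads, n_samples)
        Physical amplitudes in mV.
    """

    record_id: str
    fs: float
    lead_names: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise InputError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise InputError("samples must be a (n_leads, n_samples>=1) array")
        if len(self.lead_names) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.lead_names)} lead names for {self.samples.shape[0]} signal rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise InputError("lead names must be unique within a record")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the 1-D sample array of the named lead."""
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise InputError(
                f"lead {name!r} not in record {self.record_id!r} "
                f"(available: {', '.join(self.lead_names)})"
            ) from None


@dataclass
class BeatAnnotations:
    """Reference R-peak locations for one lead, as 0-based sample indices."""

    record_id: str
    lead_name: str
    r_samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=np.int64)
        if self.r_samples.size and np.any(np.diff(self.r_samples) <= 0):
            raise InputError("annotation sample indices must be strictly increasing")
        if self.r_samples.size and self.r_samples[0] < 0:
            raise InputError("annotation sample indices must be non-negative")
        if self.fs <= 0:
            raise InputError("sampling frequency must be positive")

    def __len__(self) -> int:
        return int(self.r_samples.size)


# ---------------------------------------------------------------------------
# WFDB (header + binary signal) reading — format 16 only


def _parse_gain_field(tok: str) -> tuple[float, int | None, str]:
    """Split a WFDB gain token ``gain(baseline)/units`` into its parts."""
    units = "mV"
    if "/" in tok:
        tok, units = tok.split("/", 1)
    baseline = None
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means the default gain
    return gain, baseline, units


def read_wfdb_record(header_path: str | os.PathLike) -> ECGRecord:
    """Read a WFDB record (``.hea`` + ``.dat``) into physical units (mV).

    Only signal format 16 (little-endian 16-bit two's complement, samples
    interleaved across signals) is supported; that is the encoding of the
    PTB Diagnostic ECG Database. Amplitudes are converted with
    ``(adc - baseline) / gain``.
    """
    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise InputError(f"header file not found: {header_path}")
    with open(header_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header: {header_path}")

    rec_fields = lines[0].split()
    if len(rec_fields) < 2:
        raise FormatError(f"malformed WFDB record line in {header_path}: {lines[0]!r}")
    record_name = rec_fields[0].split("/")[0]
    try:
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
        n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"malformed WFDB record line in {header_path}: {exc}") from exc
    if len(lines) - 1 < n_sig:
        raise FormatError(
            f"{header_path}: header declares {n_sig} signals but lists {len(lines) - 1}"
        )

    dat_files: list[str] = []
    gains = np.empty(n_sig)
    baselines = np.empty(n_sig)
    lead_names: list[str] = []
    for i, ln in enumerate(lines[1 : 1 + n_sig]):
        f = ln.split()
        if len(f) < 2:
            raise FormatError(f"{header_path}: malformed signal line {ln!r}")
        dat_files.append(f[0])
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "16":
            raise FormatError(
                f"{header_path}: signal format {fmt!r} not supported (only format 16)"
            )
        gain, baseline, _units = _parse_gain_field(f[2]) if len(f) > 2 else (200.0, None, "mV")
        if baseline is None:
            # baseline defaults to ADC zero (field 5) when not given in parens
            baseline = int(f[4]) if len(f) > 4 else 0
        gains[i] = gain
        baselines[i] = baseline
        lead_names.append(f[8] if len(f) > 8 else f"sig{i}")

    if len(set(dat_files)) != 1:
        raise FormatError(f"{header_path}: multi-file records are not supported")
    dat_path = os.path.join(os.path.dirname(header_path) or ".", dat_files[0])
    if not os.path.exists(dat_path):
        raise InputError(f"signal file not found: {dat_path}")

    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size % n_sig != 0:
        raise FormatError(
            f"{dat_path}: {raw.size} samples do not divide evenly into {n_sig} signals"
        )
    frames = raw.size // n_sig
    if n_samples and frames != n_samples:
        raise FormatError(
            f"{dat_path}: header declares {n_samples} samples/signal but file holds {frames}"
        )
    if frames == 0:
        raise FormatError(f"{dat_path}: signal file is empty")
    adc = raw.reshape(frames, n_sig).T.astype(float)
    physical = (adc - baselines[:, None]) / gains[:, None]
    return ECGRecord(record_id=record_name, fs=fs, lead_names=lead_names, samples=physical)


# ---------------------------------------------------------------------------
# CSV single-lead signals


def read_csv_signal(path: str | os.PathLike, fs: float, lead_name: str = "csv") -> ECGRecord:
    """Read a single-lead signal from text: one float per line, ``#`` comments."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"signal file not found: {path}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            try:
                values.append(float(ln))
            except ValueError:
                raise FormatError(f"{path}: non-numeric value {ln!r} on line {lineno}") from None
    if not values:
        raise InputError(f"{path}: no samples found")
    record_id = os.path.splitext(os.path.basename(path))[0]
    return ECGRecord(record_id=record_id, fs=fs, lead_names=[lead_name], samples=[values])


def write_csv_signal(x: Sequence[float], path: str | os.PathLike) -> None:
    """Write a 1-D signal as text, one sample per line (17 significant digits)."""
    arr = np.asarray(x, dtype=float).ravel()
    with open(path, "w") as fh:
        for v in arr:
            fh.write(f"{v:.17g}\n")


# ---------------------------------------------------------------------------
# Segment selection


def select_segment(
    rec: ECGRecord, start_s: float, end_s: float | str = "end"
) -> ECGRecord:
    """Cut all leads to the half-open time window ``[start_s, end_s)``.

    ``end_s`` may be the string ``"end"`` to keep everything after ``start_s``.
    """
    if start_s < 0:
        raise RangeError(f"segment start {start_s} s is negative")
    start = int(np.floor(start_s * rec.fs))
    if start >= rec.n_samples:
        raise RangeError(
            f"segment start {start_s} s is beyond record end ({rec.duration_s:.3f} s)"
        )
    if isinstance(end_s, str):
        if end_s != "end":
            raise RangeError(f"end_s must be a number or 'end', got {end_s!r}")
        stop = rec.n_samples
    else:
        if end_s <= start_s:
            raise RangeError(f"segment end {end_s} s must exceed start {start_s} s")
        stop = min(rec.n_samples, int(np.floor(end_s * rec.fs)))
    return ECGRecord(
        record_id=rec.record_id,
        fs=rec.fs,
        lead_names=list(rec.lead_names),
        samples=rec.samples[:, start:stop],
    )


# ---------------------------------------------------------------------------
# Detection / annotation text files


def _write_index_file(path, record_id: str, lead_name: str, fs: float, indices) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {record_id} {lead_name} {fs:g}\n")
        for idx in np.asarray(indices, dtype=np.int64):
            fh.write(f"{int(idx)}\n")


def _read_index_file(path) -> tuple[str, str, float, np.ndarray]:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"annotation file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: missing '# record lead fs' header line")
        parts = first[1:].split()
        if len(parts) != 3:
            raise FormatError(f"{path}: header must be '# record lead fs'")
        record_id, lead_name, fs_txt = parts
        try:
            fs = float(fs_txt)
        except ValueError:
            raise FormatError(f"{path}: non-numeric fs {fs_txt!r} in header") from None
        indices = []
        for lineno, ln in enumerate(fh, start=2):
            ln = ln.strip()
            if not ln:
                continue
            try:
                indices.append(int(ln))
            except ValueError:
                raise FormatError(f"{path}: non-integer index {ln!r} on line {lineno}") from None
    return record_id, lead_name, fs, np.asarray(indices, dtype=np.int64)


def write_detections(dets: "QRSDetections", path: str | os.PathLike) -> None:
    """Write detections as text: header line then one sample index per line."""
    _write_index_file(path, dets.record_id, dets.lead_name, dets.fs, dets.r_samples)


def read_detections(path: str | os.PathLike) -> "QRSDetections":
    """Read a detection file written by :func:`write_detections`."""
    from .detect import QRSDetections

    record_id, lead_name, fs, idx = _read_index_file(path)
    return QRSDetections(
        record_id=record_id,
        lead_name=lead_name,
        r_samples=idx,
        envelope_heights=np.full(idx.size, np.nan),
        fs=fs,
    )


def write_annotations(ann: BeatAnnotations, path: str | os.PathLike) -> None:
    """Write reference beat annotations in the same text format as detections."""
    _write_index_file(path, ann.record_id, ann.lead_name, ann.fs, ann.r_samples)


def read_annotations(path: str | os.PathLike) -> BeatAnnotations:
    """Read reference beat annotations from the plain-text index format."""
    record_id, lead_name, fs, idx = _read_index_file(path)
    return BeatAnnotations(record_id=record_id, lead_name=lead_name, r_samples=idx, fs=fs)
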