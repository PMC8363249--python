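"""Reading and writing multichannel recordings and R-peak annotations.

Two on-disk forms are supported:

* **CSV** — one column per channel with a header row of channel labels,
  plus a key--value sidecar (``<stem>.meta``) carrying the sampling rate.
  Lossless for floating point data.
* **WFDB-style** — a PhysioNet-compatible record (``<stem>.hea`` header +
  ``<stem>.dat`` format-16 interleaved int16 samples) and MIT-format binary
  annotation files.  Amplitudes are quantized by the ADC gain, exactly as in
  the standard toolkits.

All in-memory indices are 0-based sample positions; durations are seconds.
Conversion between conventions happens only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "Recording",
    "AnnotationSet",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "rescale_annotations",
]


@dataclasses.dataclass
class Recording:
    """A multichannel signal matrix (channels x samples, mV) at a fixed rate."""

    data: np.ndarray
    fs: float
    labels: list[str]
    source_id: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ParameterError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("recording contains NaN/Inf values")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclasses.dataclass
class AnnotationSet:
    """Strictly increasing R-peak sample indices referred to a sampling rate."""

    indices: np.ndarray
    fs: float
    label: str = "R"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.indices.size and np.any(self.indices < 0):
            raise ParameterError("annotation indices must be non-negative")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ParameterError("annotation indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def times(self) -> np.ndarray:
        """Annotation positions in seconds."""
        return self.indices / self.fs


# ---------------------------------------------------------------------------
# CSV + sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def _read_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"malformed sidecar line: {line!r}")
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def _read_csv(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar metadata file not found: {sidecar}")
    meta = _read_sidecar(sidecar)
    if "fs" not in meta:
        raise FormatError("sidecar is missing the sampling rate (fs)")
    fs = float(meta["fs"])
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse CSV signal file: {exc}") from exc
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise FormatError("CSV contains non-numeric cells")
    if np.any(~np.isfinite(values.astype(float))):
        raise FormatError("CSV contains NaN/Inf cells")
    return Recording(
        data=values.T.astype(float),
        fs=fs,
        labels=[str(c) for c in frame.columns],
        source_id=meta.get("source_id", path.stem),
    )


def _write_csv(rec: Recording, path: Path) -> None:
    frame = pd.DataFrame(rec.data.T, columns=rec.labels)
    # full repr round-trips float64 exactly
    frame.to_csv(path, index=False, float_format="%.17g")
    lines = [f"fs = {rec.fs!r}", f"source_id = {rec.source_id}"]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# WFDB-style record (.hea + format-16 .dat)
# ---------------------------------------------------------------------------

_WFDB_FMT = 16
_DEFAULT_GAIN = 200.0  # ADC units per mV


def _read_wfdb(path: Path) -> Recording:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"WFDB header not found: {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError("malformed WFDB header line")
    name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    gains, labels, dat_names = [], [], []
    for spec in lines[1 : 1 + n_sig]:
        fields = spec.split()
        if len(fields) < 3:
            raise FormatError(f"malformed WFDB signal line: {spec!r}")
        dat_names.append(fields[0])
        if not fields[1].startswith(str(_WFDB_FMT)):
            raise FormatError(f"unsupported WFDB sample format: {fields[1]}")
        gains.append(float(fields[2].split("/")[0].split("(")[0]) or _DEFAULT_GAIN)
        labels.append(fields[-1])
    if len(set(dat_names)) != 1:
        raise FormatError("multi-file WFDB records are not supported")
    dat = path.parent / dat_names[0]
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(
            f"WFDB signal file length mismatch: expected {n_sig * n_samp}, got {raw.size}"
        )
    digital = raw.reshape(n_samp, n_sig).T
    data = digital.astype(float) / np.asarray(gains)[:, None]
    return Recording(data=data, fs=fs, labels=labels, source_id=name)


def _write_wfdb(rec: Recording, path: Path, gain: float = _DEFAULT_GAIN) -> None:
    stem = path.with_suffix("")
    dat_name = stem.name + ".dat"
    digital = np.round(rec.data * gain)
    if np.any(np.abs(digital) > 32767):
        raise FormatError("signal exceeds int16 range at this ADC gain")
    interleaved = digital.T.astype("<i2")
    (path.parent / dat_name).write_bytes(interleaved.tobytes())
    lines = [f"{stem.name} {rec.n_channels} {rec.fs:g} {rec.n_samples}"]
    for label in rec.labels:
        lines.append(f"{dat_name} {_WFDB_FMT} {gain:g} 16 0 0 0 0 {label}")
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def read_recording(path, format: str = "csv") -> Recording:
    """Load a :class:`Recording` from ``path`` in ``csv`` or ``wfdb`` form."""
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ParameterError(f"unknown recording format: {format!r}")


def write_recording(rec: Recording, path, format: str = "csv") -> None:
    """Write ``rec`` so that :func:`read_recording` reproduces it.

    CSV is bit-faithful; WFDB quantizes amplitudes to the ADC gain
    (default 200 units/mV), matching the PhysioNet convention.
    """
    path = Path(path)
    if format == "csv":
        _write_csv(rec, path)
    elif format == "wfdb":
        _write_wfdb(rec, path)
    else:
        raise ParameterError(f"unknown recording format: {format!r}")


# ---------------------------------------------------------------------------
# MIT-format binary annotations
# ---------------------------------------------------------------------------

_ANN_NORMAL = 1   # beat annotation code
_ANN_SKIP = 59    # long interval escape


def write_annotations(ann: AnnotationSet, path) -> None:
    """Write an annotation set as an MIT-format binary annotation file."""
    out = bytearray()
    prev = 0
    for idx in ann.indices:
        delta = int(idx) - prev
        prev = int(idx)
        if delta > 1023:
            out += struct.pack("<H", _ANN_SKIP << 10)
            out += struct.pack("<I", ((delta >> 16) & 0xFFFF) << 16 | (delta & 0xFFFF))
            out += struct.pack("<H", _ANN_NORMAL << 10)
        else:
            out += struct.pack("<H", (_ANN_NORMAL << 10) | delta)
    out += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(out))


def read_annotations(path, fs: float, label: str = "R") -> AnnotationSet:
    """Read an MIT-format binary annotation file written at sampling rate ``fs``."""
    raw = Path(path).read_bytes()
    indices: list[int] = []
    pos = 0
    time = 0
    offset = 0
    while pos + 2 <= len(raw):
        (word,) = struct.unpack_from("<H", raw, pos)
        pos += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _ANN_SKIP:
            (long_word,) = struct.unpack_from("<I", raw, pos)
            pos += 4
            offset = ((long_word >> 16) & 0xFFFF) << 16 | (long_word & 0xFFFF)
            continue
        time += delta + offset
        offset = 0
        indices.append(time)
    return AnnotationSet(indices=np.asarray(indices), fs=fs, label=label)


# ---------------------------------------------------------------------------
# Annotation index rescaling
# ---------------------------------------------------------------------------

def rescale_annotations(ann: AnnotationSet, target_fs: float) -> AnnotationSet:
    """Map annotation indices to a different sampling rate.

    Each index is mapped by ``round(i * target_fs / fs)`` (NumPy round, i.e.
    half-to-even); exact duplicates created by downscaling are dropped so the
    strict-monotonicity invariant survives.
    """
    if target_fs <= 0:
        raise ParameterError("target sampling rate must be positive")
    scaled = np.round(ann.indices * (target_fs / ann.fs)).astype(np.int64)
    return AnnotationSet(indices=np.unique(scaled), fs=target_fs, label=ann.label)
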