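"""Continuous-recording container and on-disk interchange formats.

EEG is held in a :class:`Recording` — channels × samples in microvolts with
a sampling rate, channel names and stimulus-onset event markers.  On disk,
recordings travel as 16-bit EDF (the ubiquitous bedside-device format) with
a tab-separated events sidecar: EDF annotations are too lossy for rich trial
metadata, so events always live in the sidecar.

The EDF reader/writer below implements the plain EDF fixed-layout header
(256 bytes + 256 per signal) with one-second data records and int16 samples
scaled between per-channel physical extrema.  The true per-channel sample
count is stashed in the reserved header field so padded final records can be
trimmed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording", "read_recording", "write_recording", "read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    sample_rate_hz : float
    channel_names : list of str
        Defaults to the two-site montage ``["Fz", "Cz"]`` (referenced to A2).
    events : ndarray, shape (n_events, 2), int
        ``(sample_index, event_code)`` rows, strictly increasing in sample.
    meta : dict
        Free-form provenance (config echo, seeds, processing history).
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_names: list[str] = field(default_factory=lambda: ["Fz", "Cz"])
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.events.size:
            samp = self.events[:, 0]
            if samp.min() < 0 or samp.max() >= self.n_samples:
                raise ValueError("event sample indices out of range")
            if np.any(np.diff(samp) < 0):
                raise ValueError("event sample indices must be non-decreasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def copy(self, data: np.ndarray | None = None, **overrides) -> "Recording":
        """Shallow-config copy with optionally replaced data/fields."""
        kw = dict(
            data=self.data.copy() if data is None else data,
            sample_rate_hz=self.sample_rate_hz,
            channel_names=list(self.channel_names),
            events=self.events.copy(),
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return Recording(**kw)


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into an EDF numeric field of fixed ASCII width."""
    for prec in range(width - 2, -1, -1):
        s = f"{x:.{prec}f}"
        if len(s) <= width:
            return s
    return f"{x:.0e}"[:width]


def write_edf(recording: Recording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    Requires an integral sampling rate.  The final partial record is
    zero-padded; the true sample count is recorded in the reserved header
    field (``NSAMP=…``) and honoured by :func:`read_edf`.
    """
    fs = recording.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integral sampling rate, got {fs}")
    fs = int(round(fs))
    ns = recording.n_channels
    n_samples = recording.n_samples
    n_records = -(-n_samples // fs)

    pmins, pmaxs, digital = [], [], []
    for ch in recording.data:
        pmin, pmax = float(ch.min()), float(ch.max())
        if pmax <= pmin:
            pmax = pmin + 1.0
        scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
        dig = np.round((ch - pmin) / scale) + _DIG_MIN
        digital.append(np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    header_bytes = 256 + ns * 256
    parts = [
        _pad_field("0", 8),
        _pad_field("X X X X", 80),
        _pad_field("Startdate X X X X", 80),
        _pad_field("01.01.00", 8),
        _pad_field("00.00.00", 8),
        _pad_field(header_bytes, 8),
        _pad_field(f"NSAMP={n_samples}", 44),
        _pad_field(n_records, 8),
        _pad_field(1, 8),
        _pad_field(ns, 4),
    ]
    parts += [_pad_field(name, 16) for name in recording.channel_names]
    parts += [_pad_field("AgAgCl electrode", 80)] * ns
    parts += [_pad_field("uV", 8)] * ns
    parts += [_pad_field(_fmt_float(p), 8) for p in pmins]
    parts += [_pad_field(_fmt_float(p), 8) for p in pmaxs]
    parts += [_pad_field(_DIG_MIN, 8)] * ns
    parts += [_pad_field(_DIG_MAX, 8)] * ns
    parts += [_pad_field("", 80)] * ns
    parts += [_pad_field(fs, 8)] * ns
    parts += [_pad_field("", 32)] * ns

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            for dig in digital:
                chunk = dig[sl]
                if chunk.size < fs:
                    chunk = np.pad(chunk, (0, fs - chunk.size))
                fh.write(chunk.tobytes())


def read_edf(path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible).

    Supports equal per-signal sampling rates and integral 1-s (or uniform)
    record durations.  Raises a ``ValueError`` naming the byte offset of a
    malformed header field.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise ValueError(f"malformed EDF header in {path}: file shorter than 256 bytes")

    def fld(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    def intfld(offset: int, width: int) -> int:
        s = fld(offset, width)
        try:
            return int(s)
        except ValueError as err:
            raise ValueError(
                f"malformed EDF header in {path}: non-integer field {s!r} "
                f"at byte offset {offset}"
            ) from err

    header_bytes = intfld(184, 8)
    reserved = fld(192, 44)
    n_records = intfld(236, 8)
    record_dur = float(fld(244, 8) or "1")
    ns = intfld(252, 4)
    if len(raw) < header_bytes:
        raise ValueError(
            f"malformed EDF header in {path}: header claims {header_bytes} bytes, "
            f"file has {len(raw)}"
        )

    def sigfld(base: int, width: int, i: int) -> str:
        off = 256 + base * ns + width * i
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    # per-signal header blocks: label(16) transducer(80) dim(8) pmin(8)
    # pmax(8) dmin(8) dmax(8) prefilter(80) samples/record(8) reserved(32)
    labels = [sigfld(0, 16, i) for i in range(ns)]
    pmins = [float(sigfld(104, 8, i)) for i in range(ns)]
    pmaxs = [float(sigfld(112, 8, i)) for i in range(ns)]
    dmins = [int(sigfld(120, 8, i)) for i in range(ns)]
    dmaxs = [int(sigfld(128, 8, i)) for i in range(ns)]
    nsamp_rec = [int(sigfld(216, 8, i)) for i in range(ns)]
    if len(set(nsamp_rec)) != 1:
        raise ValueError("mixed per-signal record sizes are not supported")
    spr = nsamp_rec[0]
    fs = spr / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * spr * ns
    if body.size < expected:
        raise ValueError(
            f"malformed EDF in {path}: expected {expected} samples after the "
            f"header, found {body.size}"
        )
    body = body[:expected].reshape(n_records, ns, spr).astype(np.float64)
    data = np.empty((ns, n_records * spr))
    for i in range(ns):
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        data[i] = ((body[:, i, :].reshape(-1) - dmins[i]) * scale) + pmins[i]

    if reserved.startswith("NSAMP="):
        true_n = int(reserved.split("=", 1)[1])
        data = data[:, :true_n]

    return Recording(data=data, sample_rate_hz=fs, channel_names=labels)


def _events_sidecar(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + "_events.tsv")


def write_recording(recording: Recording, path) -> None:
    """Write EDF plus the ``*_events.tsv`` sidecar (sample, code, onset_s)."""
    write_edf(recording, path)
    tbl = pd.DataFrame(recording.events, columns=["sample", "code"])
    tbl["onset_s"] = tbl["sample"] / recording.sample_rate_hz
    tbl.to_csv(_events_sidecar(path), sep="\t", index=False, float_format="%.6f")


def read_recording(path) -> Recording:
    """Read EDF plus its events sidecar into a :class:`Recording`.

    A missing sidecar is an error (events are required downstream); the
    message names the expected file.
    """
    rec = read_edf(path)
    sidecar = _events_sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing events sidecar for {path}: expected {sidecar}"
        )
    tbl = pd.read_csv(sidecar, sep="\t")
    rec.events = tbl[["sample", "code"]].to_numpy(dtype=np.int64)
    return rec
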