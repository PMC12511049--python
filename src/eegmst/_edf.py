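"""Minimal reader/writer for 16-bit EDF (European Data Format).

Only the subset of the standard needed here is supported: continuous
recordings, identical sampling rate for every signal, integral record
duration. Annotations (EDF+) are not handled.
"""

from __future__ import annotations

import os

import numpy as np

from .exceptions import FormatError

_HDR_FIXED = 256
_HDR_PER_SIGNAL = 256


def _field(raw: bytes, start: int, length: int) -> str:
    return raw[start : start + length].decode("ascii", errors="replace").strip()


def _num(raw: bytes, start: int, length: int, kind=float):
    text = _field(raw, start, length)
    try:
        return kind(text)
    except ValueError as exc:  # pragma: no cover - exercised via FormatError tests
        raise FormatError(f"unparseable EDF header field {text!r}") from exc


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file.

    Returns ``(samples, rate, labels)`` with ``samples`` of shape
    ``(n_signals, n_times)`` in physical units.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(_HDR_FIXED)
        if len(fixed) < _HDR_FIXED:
            raise FormatError(f"{path}: truncated EDF header ({len(fixed)} bytes)")
        n_records = _num(fixed, 236, 8, int)
        record_dur = _num(fixed, 244, 8, float)
        n_sig = _num(fixed, 252, 4, int)
        if n_sig <= 0:
            raise FormatError(f"{path}: EDF header declares {n_sig} signals")

        sig_hdr = fh.read(_HDR_PER_SIGNAL * n_sig)
        if len(sig_hdr) < _HDR_PER_SIGNAL * n_sig:
            raise FormatError(f"{path}: truncated EDF signal header")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_sig
            return [_field(sig_hdr, base + i * width, width) for i in range(n_sig)]

        labels = col(0, 16)

        def ncol(byte_offset: int, width: int) -> np.ndarray:
            vals = []
            for i in range(n_sig):
                vals.append(float(_field(sig_hdr, byte_offset * n_sig + i * width, width)))
            return np.asarray(vals)

        phys_min = ncol(16 + 80 + 8, 8)
        phys_max = ncol(16 + 80 + 8 + 8, 8)
        dig_min = ncol(16 + 80 + 8 + 8 + 8, 8)
        dig_max = ncol(16 + 80 + 8 + 8 + 8 + 8, 8)
        spr = ncol(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8).astype(int)

        if len(set(spr.tolist())) != 1:
            raise FormatError(f"{path}: mixed per-signal sampling rates unsupported")
        samples_per_record = int(spr[0])
        if record_dur <= 0:
            raise FormatError(f"{path}: non-positive record duration")
        rate = samples_per_record / record_dur

        payload = fh.read()

    expected = n_records * n_sig * samples_per_record * 2
    if len(payload) < expected:
        raise FormatError(
            f"{path}: EDF payload truncated ({len(payload)} < {expected} bytes)"
        )
    raw = np.frombuffer(payload[:expected], dtype="<i2")
    raw = raw.reshape(n_records, n_sig, samples_per_record)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    data = raw.transpose(1, 0, 2).reshape(n_sig, -1).astype(np.float64)
    data = data * gain[:, None] + offset[:, None]
    return data, rate, labels


def write_edf(
    path: str | os.PathLike,
    samples: np.ndarray,
    rate: float,
    labels: list[str],
    subject_id: str = "X",
) -> None:
    """Write ``samples`` (n_signals, n_times) to a 16-bit EDF file.

    The tail that does not fill a whole 1-s record is dropped; physical
    ranges are chosen per channel so quantization error is ≤ range/2^16.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (signals × time)")
    n_sig, n_times = samples.shape
    if len(labels) != n_sig:
        raise ValueError("label count does not match signal count")
    samples_per_record = int(round(rate))
    if abs(samples_per_record - rate) > 1e-9:
        raise ValueError("write_edf requires an integral sampling rate")
    n_records = n_times // samples_per_record
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    samples = samples[:, : n_records * samples_per_record]

    span = np.maximum(np.abs(samples).max(axis=1), 1e-6)
    # digitize with the value as it will appear in the 8-char ASCII header,
    # otherwise reader and writer disagree on the gain
    span = np.array([float(f"{v:.6g}"[:8]) for v in span * 1.000001])
    phys_min, phys_max = -span, span
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint((samples - phys_min[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad(subject_id, 80),
            pad("eegmst synthetic", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(_HDR_FIXED + _HDR_PER_SIGNAL * n_sig), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_sig), 4),
        ]
    )

    def column(values: list[str], width: int) -> bytes:
        return b"".join(pad(v, width) for v in values)

    sig_hdr = b"".join(
        [
            column(labels, 16),
            column([""] * n_sig, 80),
            column(["uV"] * n_sig, 8),
            column([f"{v:.6g}"[:8] for v in phys_min], 8),
            column([f"{v:.6g}"[:8] for v in phys_max], 8),
            column([str(dig_min)] * n_sig, 8),
            column([str(dig_max)] * n_sig, 8),
            column([""] * n_sig, 80),
            column([str(samples_per_record)] * n_sig, 8),
            column([""] * n_sig, 32),
        ]
    )

    body = digital.reshape(n_sig, n_records, samples_per_record)
    body = body.transpose(1, 0, 2).tobytes()
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig_hdr)
        fh.write(body)
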