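"""Minimal BrainVision (.vhdr/.vmrk/.eeg) reader and fixture writer.

Supports binary multiplexed data in INT_16 or IEEE_FLOAT_32, which covers
BrainAmp exports. Marker files are required to exist but their content is
ignored (resting-state analysis uses no events).
"""

from __future__ import annotations

import configparser
import os
from pathlib import Path

import numpy as np

from .exceptions import FormatError


def _parse_ini(path: Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(strict=False)
    parser.optionxform = str  # keys are case-sensitive (Ch1 vs ch1)
    try:
        text = path.read_text(encoding="utf-8", errors="replace")
    except OSError as exc:
        raise FormatError(f"{path}: cannot read header") from exc
    # strip the "Brain Vision Data Exchange ..." banner line(s)
    lines = [ln for ln in text.splitlines() if not ln.startswith("Brain Vision")]
    try:
        parser.read_string("\n".join(lines))
    except configparser.Error as exc:
        raise FormatError(f"{path}: malformed header") from exc
    return parser


def read_brainvision(vhdr_path: str | os.PathLike) -> tuple[np.ndarray, float, list[str]]:
    """Read a BrainVision triplet given the .vhdr path.

    Returns ``(samples, rate, labels)`` with samples in µV.
    """
    vhdr = Path(vhdr_path)
    parser = _parse_ini(vhdr)
    if "Common Infos" not in parser:
        raise FormatError(f"{vhdr}: missing [Common Infos] section")
    common = parser["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise FormatError(f"{vhdr}: only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise FormatError(f"{vhdr}: only MULTIPLEXED orientation is supported")

    try:
        n_channels = int(common["NumberOfChannels"])
        sampling_interval_us = float(common["SamplingInterval"])
        data_file = common["DataFile"]
    except KeyError as exc:
        raise FormatError(f"{vhdr}: missing required key {exc}") from exc
    rate = 1e6 / sampling_interval_us

    binary_format = "INT_16"
    if "Binary Infos" in parser:
        binary_format = parser["Binary Infos"].get("BinaryFormat", "INT_16").upper()
    if binary_format not in ("INT_16", "IEEE_FLOAT_32"):
        raise FormatError(f"{vhdr}: unsupported BinaryFormat {binary_format}")

    labels: list[str] = []
    resolutions = np.ones(n_channels)
    chan_section = parser["Channel Infos"] if "Channel Infos" in parser else {}
    for i in range(n_channels):
        entry = chan_section.get(f"Ch{i + 1}", f"Ch{i + 1},,1,µV")
        parts = entry.split(",")
        labels.append(parts[0].strip() or f"Ch{i + 1}")
        if len(parts) > 2 and parts[2].strip():
            resolutions[i] = float(parts[2])

    eeg_path = vhdr.parent / data_file
    if not eeg_path.exists():
        raise FormatError(f"{vhdr}: data file {data_file} not found")
    raw = eeg_path.read_bytes()
    dtype = "<i2" if binary_format == "INT_16" else "<f4"
    flat = np.frombuffer(raw, dtype=dtype)
    if flat.size % n_channels:
        raise FormatError(f"{eeg_path}: size not a multiple of channel count")
    data = flat.reshape(-1, n_channels).T.astype(np.float64)
    if binary_format == "INT_16":
        data *= resolutions[:, None]
    return data, rate, labels


def write_brainvision(
    basepath: str | os.PathLike,
    samples: np.ndarray,
    rate: float,
    labels: list[str],
) -> Path:
    """Write a float-32 BrainVision triplet; returns the .vhdr path."""
    base = Path(basepath)
    samples = np.asarray(samples, dtype=np.float32)
    n_channels = samples.shape[0]
    if len(labels) != n_channels:
        raise ValueError("label count does not match channel count")

    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")
    eeg = base.with_suffix(".eeg")

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_channels}",
        f"SamplingInterval={1e6 / rate:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    header += [f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(labels)]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n",
        encoding="utf-8",
    )
    eeg.write_bytes(samples.T.tobytes())
    return vhdr
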