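"""Raw-recording I/O and the preprocessing chain producing analysis epochs.

The chain, in fixed order: drop ocular channels → common-average reference →
broad band-pass → downsample → (per-band band-pass) → 2-s epoching →
amplitude-based epoch rejection with a minimum-count gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._brainvision import read_brainvision
from ._edf import read_edf
from .exceptions import ContentError, FormatError, ParameterError, QualityError

GROUPS = ("HC", "MCI-AD", "AD")

#: Default labels treated as ocular channels (common BrainVision conventions).
DEFAULT_EOG_LABELS = (
    "HEOG", "VEOG", "EOG1", "EOG2", "HEOGL", "HEOGR", "VEOGU", "VEOGL",
)

#: Clinical score columns recognised in subject tables.
CLINICAL_COLUMNS = (
    "MMSE", "MoCA", "HDS-R", "CDR", "AVLT-delay", "AVLT-recog",
    "HAMA", "HAMD", "ADL",
)

#: CSF biomarker columns recognised in subject tables.
CSF_COLUMNS = ("Abeta42", "Abeta40", "t-Tau", "p-Tau")


@dataclass
class Recording:
    """A continuous multichannel recording in µV."""

    subject_id: str
    samples: np.ndarray  # (n_channels, n_times)
    rate: float
    channel_labels: list[str]
    channel_kinds: list[str]  # "EEG" or "EOG" per channel
    sensor_positions: np.ndarray | None = None  # (n_channels, 2), optional

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ContentError("samples must be channels × time")
        if self.rate <= 0:
            raise ContentError("sampling rate must be positive")
        n = self.samples.shape[0]
        if len(self.channel_labels) != n or len(self.channel_kinds) != n:
            raise ContentError("channel metadata length mismatch")
        if sum(k == "EEG" for k in self.channel_kinds) < 2:
            raise ContentError("at least 2 EEG channels required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.rate


@dataclass
class EpochSet:
    """Fixed-length artifact-screened segments of one subject."""

    subject_id: str
    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    rate: float
    epoch_duration: float
    channel_labels: list[str]
    rejection_log: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ContentError("epochs must be epoch × channel × time")
        expected = int(round(self.epoch_duration * self.rate))
        if self.epochs.shape[2] != expected:
            raise ContentError("epoch length inconsistent with duration × rate")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class SubjectRecord:
    """Group label, covariates and per-band metrics for one participant."""

    subject_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    education: float | None = None
    clinical_scores: dict[str, float] = field(default_factory=dict)
    csf: dict[str, float] = field(default_factory=dict)
    band_metrics: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ContentError(
                f"unknown group label {self.group!r}; expected one of {GROUPS}"
            )
        for name, value in {**self.clinical_scores, **self.csf}.items():
            if not math.isfinite(value):
                raise ContentError(f"non-finite value for {name!r}")


def _assign_kinds(labels: Sequence[str], eog_labels: Sequence[str]) -> list[str]:
    eog_upper = {lab.upper() for lab in eog_labels}
    kinds = []
    for lab in labels:
        up = lab.upper()
        kinds.append("EOG" if up in eog_upper or "EOG" in up else "EEG")
    return kinds


def read_recording(
    path: str | Path,
    format: str,
    subject_id: str | None = None,
    eog_labels: Sequence[str] = DEFAULT_EOG_LABELS,
) -> Recording:
    """Read an EDF or BrainVision recording and tag ocular channels by label."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    fmt = format.lower()
    if fmt == "edf":
        samples, rate, labels = read_edf(path)
    elif fmt == "brainvision":
        samples, rate, labels = read_brainvision(path)
    else:
        raise ParameterError(f"unknown format {format!r}")
    kinds = _assign_kinds(labels, eog_labels)
    if not any(k == "EEG" for k in kinds):
        raise ContentError(f"{path}: no EEG channels found")
    return Recording(
        subject_id=subject_id or path.stem,
        samples=samples,
        rate=rate,
        channel_labels=list(labels),
        channel_kinds=kinds,
    )


def drop_eog(rec: Recording) -> Recording:
    """Remove EOG-kind channels, preserving channel order."""
    keep = [i for i, k in enumerate(rec.channel_kinds) if k == "EEG"]
    positions = None
    if rec.sensor_positions is not None:
        positions = rec.sensor_positions[keep]
    return replace(
        rec,
        samples=rec.samples[keep],
        channel_labels=[rec.channel_labels[i] for i in keep],
        channel_kinds=["EEG"] * len(keep),
        sensor_positions=positions,
    )


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the average of all EEG channels (common average)."""
    eeg = [i for i, k in enumerate(rec.channel_kinds) if k == "EEG"]
    if len(eeg) < 2:
        raise ParameterError("average reference needs at least 2 EEG channels")
    out = rec.samples.copy()
    out[eeg] -= out[eeg].mean(axis=0, keepdims=True)
    return replace(rec, samples=out)


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass applied to all channels."""
    nyquist = rec.rate / 2.0
    if not (0 < low < high < nyquist):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < Nyquist ({low}, {high}, {nyquist})"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=filtered)


def downsample(rec: Recording, target_rate: float, allow_resample: bool = False) -> Recording:
    """Reduce the sampling rate.

    Integer ratios decimate by sample picking (the broad band-pass already
    removed content above the new Nyquist under defaults); other ratios
    require ``allow_resample`` and use polyphase resampling.
    """
    if target_rate > rec.rate:
        raise ParameterError("target rate above original rate")
    if target_rate == rec.rate:
        return rec
    ratio = rec.rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        out = rec.samples[:, :: int(round(ratio))]
    elif allow_resample:
        frac = _as_fraction(target_rate, rec.rate)
        out = signal.resample_poly(rec.samples, frac[0], frac[1], axis=1)
    else:
        raise ParameterError(
            f"rate {rec.rate} not an integer multiple of {target_rate}; "
            "pass allow_resample=True for polyphase resampling"
        )
    return replace(rec, samples=out, rate=target_rate)


def _as_fraction(target: float, source: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(target / source).limit_denominator(10_000)
    return frac.numerator, frac.denominator


def epoch(rec: Recording, duration: float = 2.0) -> EpochSet:
    """Cut the recording into consecutive non-overlapping epochs."""
    spe = int(round(duration * rec.rate))
    n_times = rec.samples.shape[1]
    if n_times < spe:
        raise ContentError(
            f"recording of {n_times} samples shorter than one {duration}-s epoch"
        )
    n_epochs = n_times // spe
    cut = rec.samples[:, : n_epochs * spe]
    epochs = cut.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        epochs=epochs.copy(),
        rate=rec.rate,
        epoch_duration=duration,
        channel_labels=list(rec.channel_labels),
    )


def reject_epochs(
    es: EpochSet, peak_to_peak_limit: float = 100.0, min_epochs: int = 40
) -> EpochSet:
    """Drop epochs whose worst-channel peak-to-peak amplitude exceeds the limit.

    Raises :class:`QualityError` naming the subject if fewer than
    ``min_epochs`` epochs survive.
    """
    if es.n_epochs == 0:
        raise ContentError("empty epoch set")
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # (n_epochs, n_channels)
    worst = ptp.max(axis=1)
    keep = worst <= peak_to_peak_limit
    dropped = np.nonzero(~keep)[0].tolist()
    if int(keep.sum()) < min_epochs:
        raise QualityError(
            f"subject {es.subject_id}: only {int(keep.sum())} artifact-free epochs "
            f"(minimum {min_epochs})"
        )
    return EpochSet(
        subject_id=es.subject_id,
        epochs=es.epochs[keep],
        rate=es.rate,
        epoch_duration=es.epoch_duration,
        channel_labels=list(es.channel_labels),
        rejection_log=dropped,
    )


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a delimited subject table (CSV/TSV, header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ContentError(f"{path}: missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ContentError(f"{path}: duplicate subject_id values {dupes}")

    records = []
    for _, row in df.iterrows():
        clinical = {
            name: float(row[name])
            for name in CLINICAL_COLUMNS
            if name in df.columns and pd.notna(row[name])
        }
        csf = {
            name: float(row[name])
            for name in CSF_COLUMNS
            if name in df.columns and pd.notna(row[name])
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]) if "age" in df.columns and pd.notna(row["age"]) else None,
                sex=str(row["sex"]) if "sex" in df.columns and pd.notna(row["sex"]) else None,
                education=(
                    float(row["education"])
                    if "education" in df.columns and pd.notna(row["education"])
                    else None
                ),
                clinical_scores=clinical,
                csf=csf,
            )
        )
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten SubjectRecords into a tidy DataFrame (one row per subject)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
        }
        row.update(r.clinical_scores)
        row.update(r.csf)
        rows.append(row)
    return pd.DataFrame(rows)
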