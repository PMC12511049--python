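"""Synthetic eyes-closed cohorts with known band-specific phase coupling.

Signal model per subject: for every analysis band a latent narrowband
process (white noise restricted to the band in the frequency domain) is
mixed into each EEG channel with a channel-specific constant phase offset
and an amplitude proportional to the group's coupling strength for that
band; independent broadband Gaussian noise is added per channel. Phase
offsets are applied by rotating the latent's analytic signal, which is
exact at all frequencies. Two extra ocular channels carry slow
high-amplitude artifact.

The default effect pattern raises theta coupling and lowers beta coupling
in the AD-like group, with clinical scores and CSF values generated as
linear functions of the subject's couplings plus noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import write_edf
from .connectivity import DEFAULT_BANDS, BandSpec
from .exceptions import ParameterError
from .io_preprocess import Recording, SubjectRecord

GROUPS = ("HC", "MCI-AD", "AD")

_DEFAULT_COUPLING = {
    # (group, band) -> coupling strength in [0, 1]
    ("HC", "delta"): 0.30, ("HC", "theta"): 0.30, ("HC", "alpha"): 0.40,
    ("HC", "beta"): 0.45, ("HC", "gamma"): 0.20,
    ("MCI-AD", "delta"): 0.32, ("MCI-AD", "theta"): 0.36, ("MCI-AD", "alpha"): 0.38,
    ("MCI-AD", "beta"): 0.36, ("MCI-AD", "gamma"): 0.19,
    ("AD", "delta"): 0.33, ("AD", "theta"): 0.50, ("AD", "alpha"): 0.36,
    ("AD", "beta"): 0.22, ("AD", "gamma"): 0.18,
}

# score -> (baseline at reference couplings, weight on theta, weight on beta, noise sd)
_SCORE_MODEL = {
    "MMSE": (28.0, -45.0, 30.0, 1.5),
    "MoCA": (26.5, -55.0, 35.0, 2.0),
    "HDS-R": (31.0, -60.0, 35.0, 2.0),
    "CDR": (0.05, 3.5, -1.5, 0.15),
    "AVLT-delay": (5.7, -18.0, 8.0, 1.2),
    "AVLT-recog": (22.3, -35.0, 15.0, 2.0),
    "HAMA": (4.0, 12.0, -5.0, 2.0),
    "HAMD": (4.0, 10.0, -4.0, 2.0),
    "ADL": (20.0, 30.0, -12.0, 3.0),
}
_SCORE_REF = (0.30, 0.45)  # reference (theta, beta) couplings for the baselines

# CSF link signs chosen to reproduce the reported correlation directions:
# t-Tau ~ +beta coupling, p-Tau ~ −theta coupling, Aβ1-42 ~ +theta coupling.
_CSF_MODEL = {
    "t-Tau": (640.0, 0.0, 900.0, 120.0),
    "p-Tau": (100.0, -350.0, 0.0, 30.0),
    "Abeta42": (430.0, 500.0, 0.0, 80.0),
    "Abeta40": (9500.0, 0.0, 0.0, 2500.0),
}
_CSF_REF = (0.43, 0.29)  # reference (theta, beta) couplings within the patient groups

_COVARIATES = {
    # group -> (age mean, age sd, p(female), education mean, education sd)
    "HC": (64.1, 8.2, 0.60, 13.3, 3.2),
    "MCI-AD": (67.2, 9.2, 0.47, 11.9, 3.7),
    "AD": (63.0, 8.4, 0.64, 10.7, 4.4),
}


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 30, "MCI-AD": 14, "AD": 21}
    )
    n_channels: int = 62  # EEG channels; 2 ocular channels are appended
    n_eog: int = 2
    rate: float = 1000.0
    duration: float = 480.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_COUPLING)
    )
    coupling_jitter_sd: float = 0.04
    lag_span: float = 0.75 * math.pi  # channel offsets spread over [π/8, π/8 + span]
    amp: float = 12.0  # µV amplitude of a fully coupled latent
    noise_sd: float = 10.0  # µV broadband channel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ParameterError("group sizes must be positive")
        for key, c in self.coupling.items():
            if not 0 <= c <= 1:
                raise ParameterError(f"coupling {key} = {c} outside [0, 1]")
        if self.n_channels < 2:
            raise ParameterError("need at least 2 EEG channels")

    @classmethod
    def fast_preset(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """Reduced spec (19 channels, 250 Hz, 120 s) for CI-speed runs."""
        defaults = dict(n_channels=19, rate=250.0, duration=120.0, seed=seed)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [[b.name, b.low, b.high] for b in self.bands]
        d["coupling"] = {f"{g}|{b}": v for (g, b), v in self.coupling.items()}
        return d


def _bandlimited_analytic(
    n: int, rate: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-real-power analytic signal of white noise restricted to [low, high]."""
    white = rng.standard_normal(n)
    spectrum = np.fft.fft(white)
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    keep = (freqs >= low) & (freqs <= high)  # positive frequencies only
    analytic_spectrum = np.zeros_like(spectrum)
    analytic_spectrum[keep] = 2.0 * spectrum[keep]
    z = np.fft.ifft(analytic_spectrum)
    power = np.var(z.real)
    if power <= 0:
        raise ParameterError(f"band ({low}, {high}) empty at n={n}, rate={rate}")
    return z / np.sqrt(power)


def _channel_offsets(spec: CohortSpec, band_index: int) -> np.ndarray:
    """Constant per-channel phase offsets, evenly spread and avoiding 0/π."""
    base = math.pi / 8.0 + 0.1 * band_index
    return base + spec.lag_span * np.arange(spec.n_channels) / max(spec.n_channels - 1, 1)


def draw_couplings(
    spec: CohortSpec, group: str, subject_seed: int
) -> dict[str, float]:
    """Per-subject coupling per band: group value plus clipped Gaussian jitter."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, subject_seed, 0)))
    out = {}
    for band in spec.bands:
        base = spec.coupling.get((group, band.name), 0.0)
        out[band.name] = float(np.clip(base + rng.normal(0, spec.coupling_jitter_sd), 0.0, 1.0))
    return out


def generate_subject(
    spec: CohortSpec,
    group: str,
    subject_seed: int,
    couplings: dict[str, float] | None = None,
) -> Recording:
    """Synthesize one subject's multichannel recording (EEG + ocular channels)."""
    if group not in spec.group_sizes and group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")
    if couplings is None:
        couplings = draw_couplings(spec, group, subject_seed)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, subject_seed, 1)))
    n = int(round(spec.duration * spec.rate))

    samples = rng.standard_normal((spec.n_channels, n)) * spec.noise_sd
    for b_idx, band in enumerate(spec.bands):
        latent = _bandlimited_analytic(n, spec.rate, band.low, band.high, rng)
        offsets = _channel_offsets(spec, b_idx)
        amplitude = spec.amp * couplings[band.name]
        # rotate the analytic latent into each channel: exact constant lag
        rotated = np.exp(1j * offsets)[:, None] * latent[None, :]
        samples += amplitude * rotated.real

    labels = [f"CH{i + 1:02d}" for i in range(spec.n_channels)]
    kinds = ["EEG"] * spec.n_channels
    for k in range(spec.n_eog):
        t = np.arange(n) / spec.rate
        drift = 60.0 * np.sin(2 * math.pi * 0.3 * t + rng.uniform(0, 2 * math.pi))
        blinks = np.zeros(n)
        for start in rng.integers(0, max(n - int(spec.rate), 1), size=max(int(spec.duration / 10), 1)):
            width = int(0.2 * spec.rate)
            pulse = 120.0 * np.hanning(width)
            blinks[start : start + width] += pulse[: n - start]
        eog = drift + blinks + rng.standard_normal(n) * 5.0
        samples = np.vstack([samples, eog[None, :]])
        labels.append(("VEOG", "HEOG")[k % 2])
        kinds.append("EOG")

    return Recording(
        subject_id=f"{group}{subject_seed:03d}",
        samples=samples,
        rate=spec.rate,
        channel_labels=labels,
        channel_kinds=kinds,
    )


def _covariates(group: str, rng: np.random.Generator) -> tuple[float, str, float]:
    age_m, age_sd, p_female, edu_m, edu_sd = _COVARIATES[group]
    age = float(np.clip(rng.normal(age_m, age_sd), 50, 79))
    sex = "F" if rng.random() < p_female else "M"
    education = float(np.clip(rng.normal(edu_m, edu_sd), 6, 22))
    return age, sex, education


def _scores(couplings: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
    ct, cb = couplings.get("theta", 0.0), couplings.get("beta", 0.0)
    rt, rb = _SCORE_REF
    out = {}
    for name, (base, w_theta, w_beta, sd) in _SCORE_MODEL.items():
        value = base + w_theta * (ct - rt) + w_beta * (cb - rb) + rng.normal(0, sd)
        out[name] = float(max(value, 0.0))
    return out


def _csf(couplings: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
    ct, cb = couplings.get("theta", 0.0), couplings.get("beta", 0.0)
    rt, rb = _CSF_REF
    out = {}
    for name, (base, w_theta, w_beta, sd) in _CSF_MODEL.items():
        value = base + w_theta * (ct - rt) + w_beta * (cb - rb) + rng.normal(0, sd)
        out[name] = float(max(value, 1.0))
    return out


def generate_cohort_records(
    spec: CohortSpec,
) -> list[tuple[SubjectRecord, Recording]]:
    """Generate all subjects in memory; deterministic given the spec."""
    out = []
    subject_seed = 0
    for group in ("HC", "MCI-AD", "AD"):
        if group not in spec.group_sizes:
            continue
        for _ in range(spec.group_sizes[group]):
            couplings = draw_couplings(spec, group, subject_seed)
            rec = generate_subject(spec, group, subject_seed, couplings=couplings)
            meta_rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, subject_seed, 2))
            )
            age, sex, education = _covariates(group, meta_rng)
            record = SubjectRecord(
                subject_id=rec.subject_id,
                group=group,
                age=age,
                sex=sex,
                education=education,
                clinical_scores=_scores(couplings, meta_rng),
                csf=_csf(couplings, meta_rng) if group != "HC" else {},
            )
            out.append((record, rec))
            subject_seed += 1
    return out


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write one EDF per subject plus a subject table and a manifest.

    Returns (list of EDF paths, subject-table path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    rows = []
    for record, rec in generate_cohort_records(spec):
        path = out_dir / f"{record.subject_id}.edf"
        write_edf(path, rec.samples, rec.rate, rec.channel_labels, subject_id=record.subject_id)
        paths.append(path)
        row = {
            "subject_id": record.subject_id,
            "group": record.group,
            "age": record.age,
            "sex": record.sex,
            "education": record.education,
        }
        row.update(record.clinical_scores)
        row.update(record.csf)
        rows.append(row)
    table_path = out_dir / "subjects.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    manifest = {"spec": spec.to_dict(), "n_subjects": len(paths)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths, table_path


def expected_pli_oracle(
    coupling: float,
    noise_sd: float,
    lag: float,
    n_samples: int,
    n_reps: int = 100,
    rate: float = 250.0,
    band: tuple[float, float] = (8.0, 13.0),
    amp: float = 12.0,
    filter_order: int = 4,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo reference PLI for a two-channel constant-lag model.

    Deliberately shares no code with the connectivity module: signals are
    synthesized and phase-extracted here with frequency-domain masking, and
    the sign-of-sine statistic is evaluated directly. Each rep emulates one
    estimation window of ``n_samples``; returns (mean, standard error).
    """
    if n_reps < 2:
        raise ParameterError("need at least 2 reps")
    from scipy import signal as _signal

    rng = np.random.default_rng(seed)
    sos = _signal.butter(filter_order, band, btype="bandpass", fs=rate, output="sos")

    def analytic(x: np.ndarray) -> np.ndarray:
        spectrum = np.fft.fft(x)
        n = len(x)
        mask = np.zeros(n)
        mask[1 : (n + 1) // 2] = 2.0
        mask[0] = 1.0
        if n % 2 == 0:
            mask[n // 2] = 1.0
        return np.fft.ifft(spectrum * mask)

    # pad each rep so the zero-phase filter and analytic transform settle
    pad = n_samples
    total = n_samples + 2 * pad
    values = np.empty(n_reps)
    for r in range(n_reps):
        white = rng.standard_normal(total)
        spectrum = np.fft.fft(white)
        freqs = np.fft.fftfreq(total, d=1.0 / rate)
        keep = (freqs >= band[0]) & (freqs <= band[1])
        z_spec = np.zeros_like(spectrum)
        z_spec[keep] = 2.0 * spectrum[keep]
        z = np.fft.ifft(z_spec)
        z /= np.sqrt(max(np.var(z.real), 1e-30))

        ch1 = amp * coupling * z.real + rng.standard_normal(total) * noise_sd
        ch2 = amp * coupling * (z * np.exp(-1j * lag)).real + rng.standard_normal(total) * noise_sd
        f1 = _signal.sosfiltfilt(sos, ch1)
        f2 = _signal.sosfiltfilt(sos, ch2)
        p1 = np.angle(analytic(f1))[pad : pad + n_samples]
        p2 = np.angle(analytic(f2))[pad : pad + n_samples]
        values[r] = abs(np.mean(np.sign(np.sin(p1 - p2))))
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n_reps))
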