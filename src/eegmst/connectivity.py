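"""Phase Lag Index (PLI) connectivity from band-limited epochs.

For two signals with instantaneous phase difference Δφ(t), the PLI is
|⟨sign(sin Δφ(t))⟩|: 0 for symmetric phase-difference distributions
(including strict zero lag, the volume-conduction signature) and 1 for a
consistent nonzero lag. sign(0) is taken as 0, so duplicated channels
score exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .exceptions import ContentError, ParameterError
from .io_preprocess import EpochSet


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ParameterError(f"invalid band {self.name}: ({self.low}, {self.high})")


#: The five canonical analysis bands.
DEFAULT_BANDS = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 48.0),
)


@dataclass
class PhaseSeries:
    """Instantaneous phases per epoch/channel plus retention masks."""

    phases: np.ndarray  # (n_epochs, n_channels, n_times), radians in (−π, π]
    time_mask: np.ndarray  # (n_times,) bool — samples retained for averaging
    channel_valid: np.ndarray  # (n_epochs, n_channels) bool
    channel_labels: list[str]
    band: BandSpec | None = None

    @property
    def n_epochs(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band PLI matrix with zero diagonal."""

    band: BandSpec | None
    values: np.ndarray  # (n_channels, n_channels)
    channel_labels: list[str]
    n_epochs: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContentError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ContentError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ContentError("connectivity diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ContentError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(
    es: EpochSet, band: BandSpec | None = None, edge_fraction: float = 0.05
) -> PhaseSeries:
    """Extract analytic-signal phases per epoch and channel.

    ``edge_fraction`` of the samples at each epoch boundary is flagged for
    exclusion from PLI averaging to suppress Hilbert edge effects. Channels
    with zero variance within an epoch are marked invalid for that epoch.
    """
    if not 0 <= edge_fraction < 0.5:
        raise ParameterError("edge_fraction must lie in [0, 0.5)")
    n_times = es.epochs.shape[2]
    edge = int(round(edge_fraction * n_times))
    if n_times - 2 * edge < 2:
        raise ParameterError("epoch shorter than twice the edge-exclusion window")

    analytic = hilbert(es.epochs, axis=2)
    phases = np.angle(analytic)

    time_mask = np.zeros(n_times, dtype=bool)
    time_mask[edge : n_times - edge] = True

    variances = es.epochs.var(axis=2)
    channel_valid = variances > 0
    if not channel_valid.all():
        bad = int((~channel_valid).sum())
        warnings.warn(
            f"{bad} zero-variance (epoch, channel) cells excluded from PLI averaging",
            RuntimeWarning,
            stacklevel=2,
        )
    return PhaseSeries(
        phases=phases,
        time_mask=time_mask,
        channel_valid=channel_valid,
        channel_labels=list(es.channel_labels),
        band=band,
    )


def pli_matrix(ph: PhaseSeries) -> ConnectivityMatrix:
    """PLI per channel pair: per-epoch |⟨sign sin Δφ⟩| averaged across epochs.

    Epochs in which either channel of a pair is invalid are excluded for
    that pair.
    """
    if ph.n_epochs < 1 or ph.n_channels < 2:
        raise ParameterError("need at least 1 epoch and 2 channels")
    n_ch = ph.n_channels
    total = np.zeros((n_ch, n_ch))
    counts = np.zeros((n_ch, n_ch))
    retained = np.ascontiguousarray(ph.phases[:, :, ph.time_mask])
    sin_p = np.sin(retained)
    cos_p = np.cos(retained)
    for e in range(ph.n_epochs):
        # sign(sin(φi − φj)) = sign(sin φi cos φj − cos φi sin φj)
        cross = sin_p[e][:, None, :] * cos_p[e][None, :, :]
        cross -= cos_p[e][:, None, :] * sin_p[e][None, :, :]
        per_epoch = np.abs(np.sign(cross, out=cross).mean(axis=2))
        valid = np.outer(ph.channel_valid[e], ph.channel_valid[e])
        total += np.where(valid, per_epoch, 0.0)
        counts += valid
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # symmetrize against float noise
    return ConnectivityMatrix(
        band=ph.band,
        values=values,
        channel_labels=list(ph.channel_labels),
        n_epochs=ph.n_epochs,
    )


def mean_pli(cm: ConnectivityMatrix) -> float:
    """Arithmetic mean of the strict upper triangle (global synchronization)."""
    n = cm.n_channels
    if n < 2:
        raise ParameterError("mean PLI needs at least 2 channels")
    iu = np.triu_indices(n, k=1)
    return float(cm.values[iu].mean())
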