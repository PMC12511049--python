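"""End-to-end composition: raw recording → per-band PLI → MST metrics.

The stage order is fixed: drop EOG → average reference → broad band-pass →
downsample → per-band band-pass → epoch → amplitude rejection → phase →
PLI → MST metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .connectivity import (
    DEFAULT_BANDS,
    BandSpec,
    ConnectivityMatrix,
    instantaneous_phase,
    pli_matrix,
)
from .io_preprocess import (
    DEFAULT_EOG_LABELS,
    Recording,
    bandpass,
    downsample,
    drop_eog,
    epoch,
    reject_epochs,
    rereference_average,
)
from .mst_topology import TreeMetrics, metrics_for_subject


@dataclass
class PipelineConfig:
    """Defaults mirror the acquisition/preprocessing configuration."""

    broad_band: tuple[float, float] = (0.5, 48.0)
    target_rate: float = 250.0
    epoch_duration: float = 2.0
    reject_limit: float = 100.0  # µV peak-to-peak
    min_epochs: int = 40
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    edge_fraction: float = 0.05
    filter_order: int = 4
    eog_labels: tuple[str, ...] = DEFAULT_EOG_LABELS
    distance: str = "hops"  # tree-distance convention for ecc/diameter


def preprocess_continuous(rec: Recording, config: PipelineConfig) -> Recording:
    """Stages shared by all bands: EOG drop, reference, broad filter, rate."""
    out = drop_eog(rec)
    out = rereference_average(out)
    out = bandpass(out, *config.broad_band, order=config.filter_order)
    out = downsample(out, config.target_rate)
    return out


def subject_band_connectivity(
    rec: Recording, config: PipelineConfig | None = None
) -> dict[str, ConnectivityMatrix]:
    """Per-band PLI matrices for one raw recording."""
    config = config or PipelineConfig()
    cont = preprocess_continuous(rec, config)
    out: dict[str, ConnectivityMatrix] = {}
    for band in config.bands:
        narrow = bandpass(cont, band.low, band.high, order=config.filter_order)
        es = epoch(narrow, config.epoch_duration)
        es = reject_epochs(es, config.reject_limit, config.min_epochs)
        ph = instantaneous_phase(es, band=band, edge_fraction=config.edge_fraction)
        out[band.name] = pli_matrix(ph)
    return out


def subject_metrics(
    rec: Recording, config: PipelineConfig | None = None
) -> dict[str, TreeMetrics]:
    """Per-band MST metric suites for one raw recording."""
    config = config or PipelineConfig()
    return {
        name: metrics_for_subject(cm, distance=config.distance)
        for name, cm in subject_band_connectivity(rec, config).items()
    }


def cohort_metrics_table(
    subjects: Iterable[tuple[str, Recording]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Long-format metrics table (subject, band, metric, value) for a cohort."""
    rows = []
    for subject_id, rec in subjects:
        for band_name, tm in subject_metrics(rec, config).items():
            for metric, value in tm.as_dict().items():
                rows.append(
                    {"subject": subject_id, "band": band_name, "metric": metric, "value": value}
                )
    return pd.DataFrame(rows)


def metrics_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table to one row per subject, columns ``band:metric``."""
    wide = table.pivot_table(index="subject", columns=["band", "metric"], values="value")
    wide.columns = [f"{band}:{metric}" for band, metric in wide.columns]
    return wide.reset_index()
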