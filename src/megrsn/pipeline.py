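"""High-level glue: recording -> matrices -> RSN summaries -> inference."""

from __future__ import annotations

import pandas as pd

from .bands import DEFAULT_BANDS, FrequencyBand
from .connectivity import ConnectivityMatrix, pli_matrix
from .networks import RsnDefinition, summarize_rsns
from .preprocess import RoiTimeSeriesSet, band_filter, downsample, segment_epochs
from .stats import StatReport, run_full_inference

__all__ = [
    "connectivity_for_recording",
    "cohort_summaries",
    "analyze_cohort",
]


def connectivity_for_recording(
    ts: RoiTimeSeriesSet,
    band: FrequencyBand,
    decimation: int = 1,
    n_epochs: int = 5,
    epoch_length: int = 4096,
    edge_trim: float = 0.05,
    epoch_mode: str = "average",
) -> ConnectivityMatrix:
    """Decimate, band-filter, epoch and compute the PLI matrix of one recording."""
    if decimation > 1:
        ts = downsample(ts, decimation)
    ts = band_filter(ts, band)
    epochs = segment_epochs(ts, n_epochs=n_epochs, epoch_length=epoch_length)
    return pli_matrix(epochs, edge_trim=edge_trim, epoch_mode=epoch_mode)


def cohort_summaries(
    recordings: dict,
    networks: list[RsnDefinition],
    bands=None,
    decimation: int = 1,
    n_epochs: int = 5,
    epoch_length: int = 4096,
    edge_trim: float = 0.05,
) -> pd.DataFrame:
    """RSN summary table (incl. global rows) over recordings and bands.

    ``recordings`` maps (subject, timepoint) -> RoiTimeSeriesSet.
    """
    bands = list(bands) if bands is not None else list(DEFAULT_BANDS.values())
    frames = []
    for band in bands:
        records = [
            (subject, timepoint,
             connectivity_for_recording(
                 ts, band, decimation=decimation, n_epochs=n_epochs,
                 epoch_length=epoch_length, edge_trim=edge_trim,
             ))
            for (subject, timepoint), ts in recordings.items()
        ]
        frames.append(summarize_rsns(records, networks, include_global=True))
    return pd.concat(frames, ignore_index=True)


def analyze_cohort(
    summaries: pd.DataFrame,
    cognitive_deltas: pd.DataFrame | None = None,
    alpha: float = 0.05,
    q: float = 0.05,
) -> StatReport:
    """Run the three-stage inference on a summary table."""
    return run_full_inference(summaries, cognitive_deltas, alpha=alpha, q=q)
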