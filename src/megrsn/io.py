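"""On-disk interchange: cohorts, connectivity matrices, summary tables.

A cohort directory holds one ``.npy`` array container (channels x samples)
per subject/timepoint, a delimited-text manifest, the cognitive delta table
and the RSN summary table.  Connectivity matrices travel as square
tab-separated files with a label header row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, FrequencyBand
from .connectivity import ConnectivityMatrix
from .preprocess import RoiTimeSeriesSet

__all__ = [
    "save_cohort",
    "load_cohort_recordings",
    "write_matrix",
    "read_matrix",
]


def save_cohort(cohort, directory) -> Path:
    """Write a generated cohort (recordings + tables) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for (subject, timepoint), ts in cohort.recordings.items():
        fname = f"sub{subject:02d}_{timepoint}.npy"
        np.save(directory / fname, ts.data)
        manifest_rows.append(
            (subject, timepoint, fname, ts.rate, cohort.spec.seed)
        )
    manifest = pd.DataFrame(
        manifest_rows, columns=["subject", "timepoint", "file", "rate", "seed"]
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    labels = next(iter(cohort.recordings.values())).roi_labels if cohort.recordings else ()
    (directory / "roi_labels.txt").write_text("\n".join(labels) + "\n")
    cohort.cognitive_deltas.to_csv(directory / "cognitive_deltas.csv", index=False)
    cohort.summaries.to_csv(directory / "rsn_summaries.csv", index=False)
    return directory


def load_cohort_recordings(directory) -> dict:
    """Read recordings back: (subject, timepoint) -> RoiTimeSeriesSet."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    labels = tuple(
        (directory / "roi_labels.txt").read_text().strip().splitlines()
    )
    out = {}
    for _, row in manifest.iterrows():
        data = np.load(directory / row["file"])
        out[(int(row["subject"]), str(row["timepoint"]))] = RoiTimeSeriesSet(
            labels, data, float(row["rate"])
        )
    return out


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Square tab-separated matrix with label header row and column."""
    frame = pd.DataFrame(
        matrix.values, index=matrix.roi_labels, columns=matrix.roi_labels
    )
    band = matrix.band.name if matrix.band is not None else ""
    with open(path, "w") as fh:
        fh.write(f"# band={band} n_epochs={matrix.n_epochs_averaged}\n")
        frame.to_csv(fh, sep="\t")


def read_matrix(path) -> ConnectivityMatrix:
    band: FrequencyBand | None = None
    n_epochs = 1
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#"):
            for token in header[1:].split():
                key, _, val = token.partition("=")
                if key == "band" and val:
                    band = DEFAULT_BANDS.get(val)
                elif key == "n_epochs":
                    n_epochs = int(val)
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", index_col=0)
    return ConnectivityMatrix(
        roi_labels=tuple(frame.columns),
        values=frame.to_numpy(),
        band=band,
        n_epochs_averaged=n_epochs,
    )
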