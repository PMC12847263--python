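"""Containers and text I/O for ROI time series and subject cohorts.

The atomic input of every analysis in this package is one subject's
region-of-interest (ROI) time-series matrix: ``T`` time points sampled every
``dt`` seconds for ``R`` parcellated brain regions.  Files are plain TSV
(header row = region labels, one row per time point) so that cohorts are
portable and diffable; a cohort is a directory of subject TSVs plus a JSON
manifest carrying labels, ``dt`` and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RoiTimeSeries", "Cohort", "read_timeseries", "write_timeseries"]


@dataclass
class RoiTimeSeries:
    """One subject's ROI time series.

    Parameters
    ----------
    values : ndarray of shape (T, R)
        Real BOLD-like signal, rows = time points, columns = regions.
    dt : float
        Sampling interval in seconds (fMRI repetition time).
    region_labels : sequence of str, optional
        One label per region; defaults to ``ROI_000 .. ROI_{R-1}``.
    """

    values: np.ndarray
    dt: float
    region_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D (T, R); got shape {self.values.shape}")
        if self.values.shape[0] < 2:
            raise ValueError(f"need at least 2 time points; got T={self.values.shape[0]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be a positive number of seconds; got {self.dt}")
        if self.region_labels is None:
            self.region_labels = [f"ROI_{j:03d}" for j in range(self.n_regions)]
        else:
            self.region_labels = [str(x) for x in self.region_labels]
            if len(self.region_labels) != self.n_regions:
                raise ValueError(
                    f"{len(self.region_labels)} region labels for {self.n_regions} regions"
                )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        """Highest resolvable frequency, 1/(2·dt), in Hz."""
        return 1.0 / (2.0 * self.dt)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.region_labels))


@dataclass
class Cohort:
    """A labelled collection of subjects sharing dimensions and sampling rate.

    ``labels`` uses the patient=1 / healthy-control=0 convention; ``truth``
    optionally records the effects a synthetic generator actually planted so
    recovery analyses can score themselves.
    """

    subjects: list[RoiTimeSeries]
    labels: np.ndarray
    truth: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subjects) != len(self.labels):
            raise ValueError(
                f"{len(self.subjects)} subjects but {len(self.labels)} labels"
            )
        if len(self.subjects) == 0:
            raise ValueError("empty cohort")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (patient=1, healthy=0)")
        first = self.subjects[0]
        for i, s in enumerate(self.subjects):
            if s.values.shape != first.values.shape or s.dt != first.dt:
                raise ValueError(f"subject {i} shape/dt differs from subject 0")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        return self.subjects[0].n_regions

    @property
    def n_timepoints(self) -> int:
        return self.subjects[0].n_timepoints

    @property
    def dt(self) -> float:
        return self.subjects[0].dt

    def save(self, directory: str | Path) -> None:
        """Write one TSV per subject plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, s in enumerate(self.subjects):
            name = f"subject_{i:04d}.tsv"
            write_timeseries(directory / name, s)
            names.append(name)
        manifest = {
            "subjects": names,
            "labels": self.labels.tolist(),
            "dt": self.dt,
            "truth": [t.to_dict() if hasattr(t, "to_dict") else t for t in self.truth],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        subjects = [
            read_timeseries(directory / name, dt=manifest["dt"])
            for name in manifest["subjects"]
        ]
        return cls(subjects=subjects, labels=np.asarray(manifest["labels"]),
                   truth=manifest.get("truth", []))


def read_timeseries(path: str | Path, dt: float = 2.0) -> RoiTimeSeries:
    """Read a subject TSV (header = region labels, rows = time points).

    Raises a descriptive error naming the offending cell for non-numeric
    bodies and rejects ragged or too-short files.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 time points, found {frame.shape[0]}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(frame.columns):
            for i, cell in enumerate(frame[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {i + 1}, "
                        f"column {j + 1} ({col})"
                    ) from None
        raise
    if np.any(pd.isna(values)):
        i, j = np.argwhere(pd.isna(values))[0]
        raise ValueError(f"{path}: missing value at row {i + 1}, column {j + 1}")
    return RoiTimeSeries(values=values, dt=dt, region_labels=list(frame.columns))


def write_timeseries(path: str | Path, ts: RoiTimeSeries) -> None:
    ts.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
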