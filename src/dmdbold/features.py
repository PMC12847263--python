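"""Per-region mean mode-amplitude features.

The squared magnitude ``P_ij = |φ_ij|²`` of mode i at region j measures how
strongly that dynamic pattern expresses itself in that region.  Averaging
P_ij over the retained modes gives one nonnegative number per region — the
region's mean amplitude — which is the feature classified downstream.  Two
flavours exist:

* full-band: average over every mode retained by the infra-slow band filter
  (one feature per region);
* sub-band: partition [0.01, 0.1] Hz into k equal-width bands, average
  within each band separately, and splice the k per-region blocks into a
  single R·k-dimensional vector, exposing which frequency range carries a
  group difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmd import DMD, DmdDecomposition, ModeSubset, DEFAULT_BAND
from .timeseries import Cohort

__all__ = [
    "RegionModePower",
    "BandPartition",
    "FeatureTable",
    "region_mode_power",
    "fullband_features",
    "make_band_partition",
    "subband_features",
    "assemble_feature_table",
]


@dataclass
class RegionModePower:
    """M x R matrix of per-region mode power P_ij = |φ_ij|²."""

    values: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def region_mode_power(modes: np.ndarray) -> RegionModePower:
    """P_ij = |φ_ij|² from an R x M complex mode matrix (returned M x R).

    Row i sums to the mode amplitude P_i, so this is an exact decomposition
    of each mode's power over regions.
    """
    modes = np.asarray(modes)
    return RegionModePower(values=(np.abs(modes) ** 2).T)


def fullband_features(power: RegionModePower, subset: ModeSubset) -> np.ndarray:
    """Mean of P_ij over the retained modes: one feature per region."""
    if len(subset) == 0:
        raise ValueError("cannot average over an empty mode subset")
    return power.values[subset.indices].mean(axis=0)


@dataclass
class BandPartition:
    """k equal-width frequency bands partitioning the infra-slow interval.

    Modes are assigned half-open: band b covers [edges[b], edges[b+1]), with
    the last band closed at the top edge, so every in-band mode belongs to
    exactly one band.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be at least 2 strictly increasing values")
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bands must have equal widths")

    @property
    def k(self) -> int:
        return self.edges.size - 1

    def labels(self) -> list[str]:
        return [
            f"{self.edges[b]:.3f}-{self.edges[b + 1]:.3f}Hz" for b in range(self.k)
        ]

    def assign(self, freqs: np.ndarray) -> np.ndarray:
        """Band index per frequency; -1 for frequencies outside the span."""
        freqs = np.asarray(freqs, dtype=float)
        idx = np.searchsorted(self.edges, freqs, side="right") - 1
        idx[freqs == self.edges[-1]] = self.k - 1  # top edge closed
        idx[(freqs < self.edges[0]) | (freqs > self.edges[-1])] = -1
        return idx


def make_band_partition(k: int, band: tuple[float, float] = DEFAULT_BAND) -> BandPartition:
    """Split ``band`` (default [0.01, 0.1] Hz) into k equal-width intervals."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return BandPartition(edges=np.linspace(band[0], band[1], k + 1))


def subband_features(
    power: RegionModePower, freqs: np.ndarray, partition: BandPartition
) -> np.ndarray:
    """Per-band mean of P_ij, bands spliced in ascending-frequency order.

    Each band averages over the modes whose frequency it contains (its own
    mode count, not the total).  A band containing no modes contributes a
    zero block and a warning, so band-count sweeps never abort.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size != power.n_modes:
        raise ValueError("freqs length must match number of modes in power")
    assignment = partition.assign(freqs)
    blocks = []
    for b in range(partition.k):
        hit = assignment == b
        if not np.any(hit):
            warnings.warn(
                f"band {partition.labels()[b]} contains no modes; "
                "its feature block is zero", stacklevel=2,
            )
            blocks.append(np.zeros(power.n_regions))
        else:
            blocks.append(power.values[hit].mean(axis=0))
    return np.concatenate(blocks)


@dataclass
class FeatureTable:
    """N subjects x p features with binary group labels (patient=1)."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "label", self.labels)
        return frame

    def save(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "subject", [f"subject_{i:04d}" for i in range(len(frame))])
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t")
        labels = frame["label"].to_numpy(dtype=int)
        cols = [c for c in frame.columns if c not in ("subject", "label")]
        return cls(values=frame[cols].to_numpy(dtype=float),
                   feature_names=cols, labels=labels)

    def restrict(self, indices) -> "FeatureTable":
        indices = np.asarray(indices, dtype=int)
        return FeatureTable(
            values=self.values[:, indices],
            feature_names=[self.feature_names[i] for i in indices],
            labels=self.labels.copy(),
        )


def assemble_feature_table(
    cohort: Cohort,
    mode: str = "full",
    k: int = 3,
    band: tuple[float, float] = DEFAULT_BAND,
    sv_tol: float = 1e-12,
    decompositions: list[DmdDecomposition] | None = None,
) -> FeatureTable:
    """Decompose every subject and stack mean-amplitude features.

    ``mode='full'`` yields one column per region (mean over all modes in
    ``band``); ``mode='subband'`` yields R·k columns named
    ``<band>:<region>``.  Pre-computed decompositions may be passed to avoid
    re-running DMD when both flavours are needed.
    """
    if mode not in ("full", "subband"):
        raise ValueError("mode must be 'full' or 'subband'")
    if decompositions is None:
        decompositions = [DMD(s).fit(sv_tol=sv_tol) for s in cohort.subjects]
    if len(decompositions) != len(cohort):
        raise ValueError("one decomposition per subject required")

    region_labels = cohort.subjects[0].region_labels
    partition = make_band_partition(k, band) if mode == "subband" else None
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for dec in decompositions:
            power = region_mode_power(dec.modes)
            if mode == "full":
                rows.append(fullband_features(power, dec.band_subset(band)))
            else:
                rows.append(subband_features(power, dec.freqs, partition))
    if mode == "full":
        names = list(region_labels)
    else:
        names = [f"{blab}:{rlab}" for blab in partition.labels()
                 for rlab in region_labels]
    return FeatureTable(values=np.vstack(rows), feature_names=names,
                        labels=cohort.labels.copy())
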