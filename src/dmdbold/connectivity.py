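"""Functional connectivity and mode-based connectivity.

Functional connectivity (FC) is the standard R x R Pearson correlation
matrix of the raw region time courses.  The mode-based analogue ("phiC")
asks the same synchronization question of the decomposition instead of the
data: region j's "mode sequence" is row j of the (band-filtered) complex
mode matrix, and two regions are similar when their rows point the same way.

Because region j's time course is Re(sum_i phi_ji * d_i(t)) with temporal
factors d_i(t) = b_i * lambda_i^{t/dt} that each have approximately zero
temporal mean and near-orthogonal waveforms, the time-domain Pearson
correlation of two regions maps onto the *uncentered* conjugate cosine
similarity of their mode rows — centering across the mode index has no
time-domain counterpart and is deliberately omitted.  The real part is
taken so the matrix is symmetric with unit diagonal.  Empirically phiC
tracks FC almost perfectly on noiseless periodic cohorts, and the match is
quantified here by the Pearson r and RMSE over strictly-upper-triangle
entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmd import DmdDecomposition, ModeSubset
from .timeseries import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "ComparisonStats",
    "functional_connectivity",
    "mode_sequence_correlation",
    "compare_connectivity",
]


@dataclass
class ConnectivityMatrix:
    """R x R symmetric matrix with unit diagonal; ``kind`` is 'FC' or 'phiC'."""

    values: np.ndarray
    kind: str
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        R = self.values.shape[0]
        if self.values.shape != (R, R):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        labels = self.region_labels or [f"ROI_{j:03d}" for j in range(self.n_regions)]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def _zero_variance_guard(matrix: np.ndarray, bad: np.ndarray, kind: str) -> np.ndarray:
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} constant/zero-variance region(s) in {kind}; "
            "their correlations are set to 0", stacklevel=3,
        )
        matrix[bad, :] = 0.0
        matrix[:, bad] = 0.0
        np.fill_diagonal(matrix, 1.0)
    return matrix


def functional_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of region time courses."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation")
    values = ts.values
    sd = values.std(axis=0)
    bad = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = _zero_variance_guard(corr, bad, "FC")
    # exact symmetry despite float round-off
    corr = (corr + corr.T) / 2.0
    return ConnectivityMatrix(values=corr, kind="FC",
                              region_labels=list(ts.region_labels))


def mode_sequence_correlation(
    dec: DmdDecomposition, subset: ModeSubset | None = None
) -> ConnectivityMatrix:
    """Similarity of regions' complex mode rows (phiC).

    r_jk = Re(<row_j, conj(row_k)>) / (||row_j|| ||row_k||) over the modes in
    ``subset`` (default: all modes).  Rows are not centered (see module
    docstring); zero rows are handled like constant series in FC.
    """
    if subset is None:
        subset = ModeSubset(indices=np.arange(dec.n_modes))
    if len(subset) < 2:
        raise ValueError("need at least 2 modes for a mode-sequence correlation")
    M = dec.modes[:, subset.indices]  # (R, M_s)
    G = M @ M.conj().T
    norms = np.sqrt(np.real(np.diag(G)))
    bad = norms == 0
    norms_safe = np.where(bad, 1.0, norms)
    corr = np.real(G) / np.outer(norms_safe, norms_safe)
    np.fill_diagonal(corr, 1.0)
    corr = _zero_variance_guard(corr, bad, "phiC")
    corr = (corr + corr.T) / 2.0
    return ConnectivityMatrix(values=corr, kind="phiC",
                              region_labels=list(dec.region_labels) or None)


@dataclass
class ComparisonStats:
    """Agreement between two connectivity matrices on off-diagonal entries."""

    pearson_r: float
    rmse: float


def compare_connectivity(a: ConnectivityMatrix, b: ConnectivityMatrix) -> ComparisonStats:
    """Pearson r and RMSE over strictly-upper-triangle entries."""
    if a.values.shape != b.values.shape:
        raise ValueError("connectivity matrices differ in shape")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    r = float(np.corrcoef(ua, ub)[0, 1])
    rmse = float(np.sqrt(np.mean((ua - ub) ** 2)))
    return ComparisonStats(pearson_r=r, rmse=rmse)
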