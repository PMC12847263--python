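"""Exact dynamic mode decomposition with scaled modes.

Given one subject's ROI series, the snapshot matrices are

    X  = [x_1 ... x_{T-1}],   X' = [x_2 ... x_T]      (R x (T-1) each),

and the data are assumed to follow the linear evolution X' = A X.  With the
thin SVD ``X = U S V*`` the algorithm forms the reduced operator
``A~ = U* X' V S^{-1}``, rescales it to ``A^ = S^{-1/2} A~ S^{1/2}``, takes
the eigendecomposition ``A^ W^ = W^ Λ``, scales the eigenvectors back with
``W = S^{1/2} W^`` and maps them into region space:

    Φ = X' V S^{-1} W.

Each column φ_i of Φ is a DMD mode with eigenvalue λ_i.  The ``S^{1/2}``
rescaling makes mode magnitudes comparable across modes, so the squared
column norm ``P_i = ||φ_i||²`` acts like a power spectrum over dynamic
patterns.  The eigenvalue supplies the temporal oscillation frequency

    f_i = | imag(log λ_i) / dt | / (2π)     (Hz, principal branch),

and the decomposition gives an explicit signal model

    x(t) = Φ Λ^{t/dt} b,      b = Φ⁺ x(0),

used for reconstruction inside the fitted window and forecasting beyond it.
Φ is R x M and not square, so the Moore-Penrose pseudoinverse replaces the
inverse; when only a subset of modes is used, b is re-fit from that subset's
pseudoinverse (the least-squares projection of x(0) onto the retained
modes), not by zeroing entries of the full-mode b.

For real-valued input the spectrum is closed under conjugation: genuinely
oscillatory modes come in conjugate pairs with equal frequency and equal
amplitude, which is why band filtering keeps or drops partners together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeries

__all__ = [
    "SnapshotPair",
    "DmdDecomposition",
    "DMDResults",
    "ModeSubset",
    "DMD",
    "build_snapshots",
    "exact_dmd",
    "mode_frequencies",
    "mode_amplitudes",
    "band_filter_modes",
    "reconstruct_signal",
    "predict_and_score",
]

logger = logging.getLogger(__name__)

#: canonical infra-slow resting-state band (Hz), closed on both ends
DEFAULT_BAND = (0.01, 0.1)


@dataclass
class SnapshotPair:
    """Time-shifted snapshot matrices X (columns x_1..x_{T-1}) and X'."""

    X: np.ndarray
    Xp: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != self.Xp.shape:
            raise ValueError("X and X' must have identical shapes")


def build_snapshots(ts: RoiTimeSeries) -> SnapshotPair:
    """Transpose the (T, R) series into the R x (T-1) snapshot pair."""
    data = ts.values.T  # (R, T)
    return SnapshotPair(X=data[:, :-1].copy(), Xp=data[:, 1:].copy())


def mode_frequencies(eigvals: np.ndarray, dt: float) -> np.ndarray:
    """Oscillation frequency of each eigenvalue, |Im(log λ)/dt|/(2π) in Hz.

    Uses the principal branch of the complex logarithm, so frequencies lie
    in [0, 1/(2·dt)].  Eigenvalues on the negative real axis alias to the
    Nyquist frequency and are logged as a warning; zero eigenvalues have no
    defined frequency and raise.
    """
    eigvals = np.asarray(eigvals, dtype=complex)
    if np.any(eigvals == 0):
        raise ValueError("zero eigenvalue: log(λ) undefined")
    n_neg_real = int(np.sum((eigvals.real < 0) & (eigvals.imag == 0)))
    if n_neg_real:
        logger.warning(
            "%d eigenvalue(s) on the negative real axis map to the Nyquist "
            "frequency", n_neg_real,
        )
    return np.abs(np.log(eigvals).imag / dt) / (2.0 * np.pi)


def mode_amplitudes(modes: np.ndarray) -> np.ndarray:
    """Amplitude P_i of each mode: squared 2-norm of column φ_i."""
    modes = np.asarray(modes)
    return np.sum(np.abs(modes) ** 2, axis=0)


@dataclass
class ModeSubset:
    """A sorted, duplicate-free selection of mode indices, optionally
    tagged with the frequency band that produced it."""

    indices: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("duplicate mode indices")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class DmdDecomposition:
    """Results of exact DMD on one subject.

    Attributes
    ----------
    modes : (R, M) complex ndarray
        Scaled DMD modes Φ, one column per mode.
    eigvals : (M,) complex ndarray
        Discrete-time eigenvalues λ_i.
    freqs : (M,) ndarray
        Oscillation frequencies in Hz.
    amplitudes : (M,) ndarray
        Mode amplitudes P_i = ||φ_i||².
    singular_values : ndarray
        Retained singular values of the snapshot matrix X.
    rank : int
        Number of retained modes M.
    dt : float
        Sampling interval in seconds.

    Modes are ordered by ascending frequency, ties broken by descending
    amplitude, so output files are reproducible across runs.
    """

    modes: np.ndarray
    eigvals: np.ndarray
    freqs: np.ndarray
    amplitudes: np.ndarray
    singular_values: np.ndarray
    rank: int
    dt: float
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.modes.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.dt)

    def band_subset(self, band: tuple[float, float] = DEFAULT_BAND) -> ModeSubset:
        return band_filter_modes(self, band)

    def reconstruct(self, x0: np.ndarray, t: float,
                    subset: ModeSubset | None = None) -> np.ndarray:
        if subset is None:
            subset = ModeSubset(indices=np.arange(self.n_modes))
        return reconstruct_signal(self, subset, x0, t)

    def reconstruct_series(self, x0: np.ndarray, times: np.ndarray,
                           subset: ModeSubset | None = None) -> np.ndarray:
        """Vectorized reconstruction at many times; rows = time points."""
        if subset is None:
            subset = ModeSubset(indices=np.arange(self.n_modes))
        if len(subset) == 0:
            raise ValueError("cannot reconstruct from an empty mode subset")
        phi = self.modes[:, subset.indices]
        lam = self.eigvals[subset.indices]
        b, *_ = np.linalg.lstsq(phi, np.asarray(x0, dtype=complex), rcond=None)
        powers = np.asarray(times, dtype=float)[:, None] / self.dt  # (n_t, 1)
        dyn = np.exp(powers * np.log(lam)[None, :]) * b[None, :]  # (n_t, M_s)
        out = dyn @ phi.T  # (n_t, R)
        imag_resid = float(np.max(np.abs(out.imag), initial=0.0))
        if imag_resid > 1e-6 * max(1.0, float(np.max(np.abs(out.real)))):
            logger.warning("reconstruction imaginary residual %.3g", imag_resid)
        return out.real

    def summary(self) -> pd.DataFrame:
        """Per-mode table: frequency, |λ|, amplitude, share of total power."""
        total = float(np.sum(self.amplitudes))
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "eig_modulus": np.abs(self.eigvals),
                "amplitude": self.amplitudes,
                "power_share": self.amplitudes / total if total > 0 else 0.0,
            }
        )

    def __str__(self) -> str:
        nb = len(self.band_subset())
        return (
            f"DmdDecomposition: {self.n_modes} modes over {self.n_regions} "
            f"regions (dt={self.dt} s, {nb} modes in "
            f"[{DEFAULT_BAND[0]}, {DEFAULT_BAND[1]}] Hz)"
        )


# alias used by the model-style API: DMD(ts).fit() returns the results object
DMDResults = DmdDecomposition


def exact_dmd(
    pair: SnapshotPair,
    dt: float,
    rank: int | None = None,
    sv_tol: float = 1e-12,
    region_labels: list[str] | None = None,
) -> DmdDecomposition:
    """Exact DMD of a snapshot pair with scaled modes.

    Singular values below ``sv_tol`` times the largest are discarded (they
    would blow up S^{-1}); ``rank`` optionally caps the retained count.  By
    default nothing else is truncated, so a full-rank T-point subject yields
    exactly T-1 modes.
    """
    X, Xp = pair.X, pair.Xp
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("all-zero snapshot matrix: DMD undefined")
    keep = s > sv_tol * s[0]
    r = int(np.count_nonzero(keep))
    if rank is not None:
        if rank > r:
            raise ValueError(f"requested rank {rank} exceeds retained rank {r}")
        r = rank
    U, s, Vh = U[:, :r], s[:r], Vh[:r, :]

    s_inv = 1.0 / s
    s_sqrt = np.sqrt(s)
    atilde = U.conj().T @ Xp @ Vh.conj().T * s_inv[None, :]
    ahat = (atilde * s_sqrt[None, :]) / s_sqrt[:, None]  # S^{-1/2} A~ S^{1/2}
    lam, what = np.linalg.eig(ahat)
    W = what * s_sqrt[:, None]  # S^{1/2} W^
    phi = Xp @ Vh.conj().T @ (W * s_inv[:, None])  # X' V S^{-1} W

    freqs = mode_frequencies(lam, dt)
    amps = mode_amplitudes(phi)
    order = np.lexsort((-amps, freqs))
    return DmdDecomposition(
        modes=phi[:, order],
        eigvals=lam[order],
        freqs=freqs[order],
        amplitudes=amps[order],
        singular_values=s,
        rank=r,
        dt=dt,
        region_labels=list(region_labels or []),
    )


class DMD:
    """Exact dynamic mode decomposition of one subject's ROI time series.

    Model-style front end: construct from a :class:`RoiTimeSeries` (or a
    plain (T, R) array plus ``dt``) and call :meth:`fit` to obtain a
    :class:`DMDResults` carrying modes, eigenvalues, frequencies and
    amplitudes, with reconstruction/forecasting methods.

    Examples
    --------
    >>> model = DMD(ts)
    >>> res = model.fit()
    >>> res.n_modes          # T - 1 for full-rank input
    >>> sub = res.band_subset((0.01, 0.1))
    >>> xhat = res.reconstruct_series(ts.values[0], times, subset=sub)
    """

    def __init__(self, ts, dt: float | None = None, region_labels=None):
        if isinstance(ts, RoiTimeSeries):
            self.ts = ts
        else:
            if dt is None:
                raise ValueError("dt is required when passing a plain array")
            self.ts = RoiTimeSeries(values=np.asarray(ts, dtype=float), dt=dt,
                                    region_labels=region_labels)

    def fit(self, rank: int | None = None, sv_tol: float = 1e-12) -> DMDResults:
        pair = build_snapshots(self.ts)
        return exact_dmd(pair, dt=self.ts.dt, rank=rank, sv_tol=sv_tol,
                         region_labels=list(self.ts.region_labels))


def band_filter_modes(dec: DmdDecomposition,
                      band: tuple[float, float] = DEFAULT_BAND) -> ModeSubset:
    """Indices of modes with frequency inside the closed interval ``band``.

    Conjugate partners share a frequency, so they are always kept or dropped
    together.  An empty result is a warning, not an error: the caller may be
    sweeping bands.
    """
    lo, hi = band
    if not (0 <= lo <= hi <= dec.nyquist + 1e-12):
        raise ValueError(f"band {band} outside [0, Nyquist={dec.nyquist}]")
    idx = np.flatnonzero((dec.freqs >= lo) & (dec.freqs <= hi))
    if idx.size == 0:
        warnings.warn(f"no modes in band {band}", stacklevel=2)
    return ModeSubset(indices=idx, band=(lo, hi))


def reconstruct_signal(dec: DmdDecomposition, subset: ModeSubset,
                       x0: np.ndarray, t: float) -> np.ndarray:
    """Signal at time ``t`` (seconds) from the retained modes:
    x(t) = Φ_s Λ_s^{t/dt} Φ_s⁺ x(0), real part."""
    if len(subset) == 0:
        raise ValueError("cannot reconstruct from an empty mode subset")
    return dec.reconstruct_series(x0, np.asarray([float(t)]), subset=subset)[0]


def predict_and_score(
    ts: RoiTimeSeries,
    n_train: int,
    band: tuple[float, float] | None = None,
    sv_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit DMD on the first ``n_train`` points and score forecasts beyond.

    The decomposition of points 0..n_train-1 is extrapolated to the held-out
    points via the explicit signal model; the return value is the per-horizon
    root-mean-square error over regions (horizon h = point n_train-1+h) and a
    boolean flag per horizon marking RMSE > 1, the conventional cut for
    "prediction has failed" when summarising forecast curves.
    """
    T = ts.n_timepoints
    if not (2 <= n_train < T):
        raise ValueError(f"n_train must be in [2, {T - 1}]; got {n_train}")
    train = RoiTimeSeries(values=ts.values[:n_train], dt=ts.dt,
                          region_labels=ts.region_labels)
    dec = DMD(train).fit(sv_tol=sv_tol)
    subset = dec.band_subset(band) if band is not None else None
    times = np.arange(n_train, T) * ts.dt
    pred = dec.reconstruct_series(ts.values[0], times, subset=subset)
    truth = ts.values[n_train:]
    rmse = np.sqrt(np.mean((pred - truth) ** 2, axis=1))
    return rmse, rmse > 1.0
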