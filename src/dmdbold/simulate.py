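"""Synthetic cohort generators.

Two generators cover the two roles synthetic data plays here:

* :func:`generate_sinusoid_cohort` builds cohorts with the statistical
  structure the downstream analysis assumes about resting-state BOLD at the
  ROI level — oscillations concentrated in the infra-slow 0.01–0.1 Hz band,
  values concentrated in roughly [-10, 10], two groups with planted
  region- and band-specific amplitude effects, plus out-of-band components
  and additive noise.
* :func:`generate_linear_system_cohort` produces trajectories of an exactly
  linear dynamical system with prescribed eigenvalues, the natural oracle
  for dynamic mode decomposition: recovered eigenvalues, reconstructions and
  forecasts can be compared against closed-form truth.

Determinism: a single cohort seed is expanded into independent per-subject
streams with :class:`numpy.random.SeedSequence` spawning, so cohorts are
bit-reproducible and subjects could be generated in parallel without
changing the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .timeseries import Cohort, RoiTimeSeries

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "generate_sinusoid_cohort",
    "generate_linear_system_cohort",
    "DEFAULT_FREQ_GRID",
]

#: Nine oscillation frequencies strictly inside the 0.01–0.1 Hz infra-slow
#: band plus one component strictly outside it, so band-filtering decisions
#: are never made at an interval boundary.
DEFAULT_FREQ_GRID: tuple[float, ...] = tuple(np.linspace(0.015, 0.095, 9)) + (0.15,)

#: Frequencies above this are treated as out-of-band by the generator when
#: deciding which components get ``out_of_band_sd`` amplitude.
_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference: in ``band`` (Hz), the patient group's
    oscillation amplitude at ``region_index`` is multiplied by
    ``1 + direction * relative_magnitude``.

    ``direction=+1`` means patients higher, ``-1`` patients lower; the
    product must stay above -1 so amplitudes remain nonnegative.
    """

    region_index: int
    band: tuple[float, float]
    direction: int = 1
    relative_magnitude: float = 0.5

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if not np.isfinite(self.relative_magnitude) or self.relative_magnitude == 0:
            raise ValueError("relative_magnitude must be finite and nonzero")
        if self.direction * self.relative_magnitude <= -1:
            raise ValueError("effect would make amplitude negative")
        lo, hi = self.band
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
            raise ValueError(f"invalid effect band {self.band}")

    @property
    def multiplier(self) -> float:
        return 1.0 + self.direction * self.relative_magnitude

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortSpec:
    """Full description of a two-group sinusoid cohort.

    Defaults emulate the dimensions and signal scale of a 300-region,
    140-time-point resting-state acquisition at a 2 s repetition time, with
    equal groups and per-region base amplitudes giving signal values
    concentrated in [-10, 10].
    """

    n_per_group: int = 68
    R: int = 300
    T: int = 140
    dt: float = 2.0
    freq_grid: tuple[float, ...] = DEFAULT_FREQ_GRID
    base_amplitude: np.ndarray | float = 2.0
    noise_sd: float = 0.5
    out_of_band_sd: float = 0.5
    signal_scale: tuple[float, float] = (-10.0, 10.0)
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be positive")
        nyq = 1.0 / (2.0 * self.dt)
        grid = np.asarray(self.freq_grid, dtype=float)
        if grid.size == 0 or not np.all(np.isfinite(grid)):
            raise ValueError("freq_grid must be non-empty and finite")
        if np.any(grid <= 0) or np.any(grid > nyq):
            raise ValueError(f"freq_grid values must lie in (0, {nyq}] Hz")
        self.freq_grid = tuple(grid)
        amp = np.broadcast_to(
            np.asarray(self.base_amplitude, dtype=float), (self.R,)
        ).copy()
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ValueError("base_amplitude must be finite and nonnegative")
        self.base_amplitude = amp
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and nonnegative")
        if not np.isfinite(self.out_of_band_sd) or self.out_of_band_sd < 0:
            raise ValueError("out_of_band_sd must be finite and nonnegative")
        for eff in self.effects:
            if not (0 <= eff.region_index < self.R):
                raise ValueError(f"effect region {eff.region_index} outside 0..{self.R - 1}")
            lo, hi = eff.band
            covered = [f for f in self.freq_grid if lo <= f <= hi]
            if not covered:
                raise ValueError(
                    f"effect band {eff.band} covers no freq_grid frequency: "
                    "there is no oscillator to modulate"
                )


def _component_amplitudes(spec: CohortSpec) -> np.ndarray:
    """(F, R) base amplitude of each frequency component in each region."""
    grid = np.asarray(spec.freq_grid)
    in_band = (grid >= _BAND[0]) & (grid <= _BAND[1])
    amp = np.empty((grid.size, spec.R))
    amp[in_band, :] = spec.base_amplitude[None, :]
    amp[~in_band, :] = spec.out_of_band_sd
    return amp


def generate_sinusoid_cohort(spec: CohortSpec) -> Cohort:
    """Generate a two-group cohort of band-limited oscillatory subjects.

    Each region's series is a sum of sinusoids at ``spec.freq_grid``
    frequencies with phases drawn i.i.d. uniform on [0, 2π) per
    subject/region/frequency (subjects must differ: real resting-state modes
    show strong inter-subject variability), plus i.i.d. Gaussian noise.
    For patient-group subjects, components whose frequency falls inside an
    effect band have their amplitude at the effect region multiplied by
    ``1 + direction·relative_magnitude``; control subjects are untouched.

    The first ``n_per_group`` subjects are controls (label 0), the rest
    patients (label 1).  Deterministic given ``spec.seed``.
    """
    grid = np.asarray(spec.freq_grid)
    t = np.arange(spec.T) * spec.dt  # seconds
    base = _component_amplitudes(spec)  # (F, R)

    patient_amp = base.copy()
    for eff in spec.effects:
        lo, hi = eff.band
        hit = (grid >= lo) & (grid <= hi)
        patient_amp[hit, eff.region_index] *= eff.multiplier

    n_total = 2 * spec.n_per_group
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    labels = np.repeat([0, 1], spec.n_per_group)
    phase_arg = 2.0 * np.pi * grid[:, None] * t[None, :]  # (F, T)

    subjects = []
    for label, stream in zip(labels, streams):
        rng = np.random.default_rng(stream)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(grid.size, spec.R))
        amp = patient_amp if label == 1 else base
        # (T, R): sum over frequency components of a_f sin(2π f t + φ)
        values = np.einsum(
            "fr,ftr->tr", amp, np.sin(phase_arg[:, :, None] + phases[:, None, :])
        )
        if spec.noise_sd > 0:
            values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
        subjects.append(RoiTimeSeries(values=values, dt=spec.dt))
    return Cohort(subjects=subjects, labels=labels, truth=list(spec.effects))


def _real_block_matrix(eigvals: np.ndarray) -> np.ndarray:
    """Real block-diagonal matrix with the given spectrum.

    Real eigenvalues become 1x1 blocks; complex ones must arrive in
    conjugate pairs and become 2x2 rotation-scaling blocks
    ``[[a, b], [-b, a]]`` for λ = a + bi.
    """
    eigvals = np.asarray(eigvals, dtype=complex)
    remaining = list(eigvals)
    blocks: list[np.ndarray] = []
    tol = 1e-12
    while remaining:
        lam = remaining.pop(0)
        if abs(lam.imag) <= tol:
            blocks.append(np.array([[lam.real]]))
            continue
        # find the conjugate partner
        match = None
        for i, other in enumerate(remaining):
            if abs(other - np.conj(lam)) <= 1e-9 * max(1.0, abs(lam)):
                match = i
                break
        if match is None:
            raise ValueError(
                f"complex eigenvalue {lam} has no conjugate partner; the "
                "generated system would not be real-valued"
            )
        remaining.pop(match)
        a, b = lam.real, abs(lam.imag)
        blocks.append(np.array([[a, b], [-b, a]]))
    out = np.zeros((len(eigvals), len(eigvals)))
    pos = 0
    for blk in blocks:
        k = blk.shape[0]
        out[pos : pos + k, pos : pos + k] = blk
        pos += k
    return out


def generate_linear_system_cohort(
    n_subjects: int,
    R: int,
    T: int,
    dt: float,
    eigvals,
    seed: int = 0,
    x0_scale: float = 1.0,
    noise_sd: float = 0.0,
    target_rms: float | None = None,
) -> Cohort:
    """Cohort of trajectories of ``x_{k+1} = A x_k`` with prescribed spectrum.

    ``A`` embeds the real block-diagonal form of ``eigvals`` into R
    dimensions through a random orthogonal similarity (one draw per cohort);
    per-subject initial states are random within the excited subspace, so
    every trajectory is an exact rank-``len(eigvals)`` linear system.
    ``target_rms`` optionally rescales each subject so its root-mean-square
    value matches (the noiseless part is scaled; noise is added after).
    All labels are 0 — these cohorts exercise the decomposition, not the
    group comparison.
    """
    eigvals = np.asarray(eigvals, dtype=complex)
    K = eigvals.size
    if K < 1:
        raise ValueError("need at least one eigenvalue")
    if R < K:
        raise ValueError(f"R={R} smaller than number of eigenvalues {K}")
    if T < 2:
        raise ValueError("T must be >= 2")
    if np.any(np.abs(eigvals) > 1.0 + 1e-12):
        raise ValueError("eigenvalues must satisfy |λ| <= 1 (stable/marginal)")

    block = _real_block_matrix(eigvals)  # (K, K)
    ss = np.random.SeedSequence(seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    # random orthogonal basis for the embedding
    Q, _ = np.linalg.qr(cohort_rng.standard_normal((R, K)))

    streams = np.random.SeedSequence(entropy=seed, spawn_key=(1,)).spawn(n_subjects)
    subjects = []
    for stream in streams:
        rng = np.random.default_rng(stream)
        z = rng.standard_normal(K) * x0_scale
        traj = np.empty((T, K))
        traj[0] = z
        for k in range(1, T):
            traj[k] = block @ traj[k - 1]
        values = traj @ Q.T  # (T, R)
        if target_rms is not None:
            rms = np.sqrt(np.mean(values**2))
            if rms > 0:
                values *= target_rms / rms
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        subjects.append(RoiTimeSeries(values=values, dt=dt))
    return Cohort(subjects=subjects, labels=np.zeros(n_subjects, dtype=int))
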