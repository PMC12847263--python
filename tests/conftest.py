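import logging

import numpy as np
import pytest

from dmdbold import (CohortSpec, EffectSpec, generate_linear_system_cohort,
                     generate_sinusoid_cohort)

# silence the per-decomposition Nyquist-aliasing log lines in test output
logging.getLogger("dmdbold").setLevel(logging.ERROR)

IN_BAND_FREQS = np.linspace(0.015, 0.095, 9)


def rotation_eigvals(freqs, dt=2.0, radius=1.0):
    """Conjugate eigenvalue pairs for pure oscillations at the given Hz."""
    out = []
    for f in np.atleast_1d(freqs):
        out += [radius * np.exp(1j * 2 * np.pi * f * dt),
                radius * np.exp(-1j * 2 * np.pi * f * dt)]
    return out


FIVE_EFFECTS = [
    EffectSpec(region_index=5, band=(0.01, 0.04), direction=1, relative_magnitude=0.5),
    EffectSpec(region_index=42, band=(0.04, 0.07), direction=-1, relative_magnitude=0.5),
    EffectSpec(region_index=77, band=(0.07, 0.1), direction=1, relative_magnitude=0.5),
    EffectSpec(region_index=150, band=(0.01, 0.04), direction=-1, relative_magnitude=0.5),
    EffectSpec(region_index=260, band=(0.07, 0.1), direction=1, relative_magnitude=0.5),
]


@pytest.fixture(scope="session")
def linear_cohort():
    """Exact linear-dynamics subjects: 5 subjects, 40 regions, 80 points."""
    return generate_linear_system_cohort(
        5, R=40, T=80, dt=2.0, eigvals=rotation_eigvals(IN_BAND_FREQS),
        seed=11, target_rms=5.0)


@pytest.fixture(scope="session")
def noiseless_sine_cohort():
    """4 noiseless periodic subjects at full 300-region scale."""
    spec = CohortSpec(n_per_group=2, noise_sd=0.0, out_of_band_sd=0.0, seed=21)
    return generate_sinusoid_cohort(spec)


@pytest.fixture(scope="session")
def small_planted_cohort():
    """Compact planted cohort for feature/selection tests (R=60)."""
    effects = [
        EffectSpec(region_index=5, band=(0.01, 0.04), direction=1,
                   relative_magnitude=0.5),
        EffectSpec(region_index=17, band=(0.07, 0.1), direction=-1,
                   relative_magnitude=0.5),
    ]
    spec = CohortSpec(n_per_group=25, R=60, effects=effects, seed=31)
    return generate_sinusoid_cohort(spec), effects
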