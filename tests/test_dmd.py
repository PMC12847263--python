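import numpy as np
import pytest

from dmdbold import (DMD, ModeSubset, RoiTimeSeries, band_filter_modes,
                     build_snapshots, exact_dmd, generate_linear_system_cohort,
                     generate_sinusoid_cohort, CohortSpec, mode_amplitudes,
                     mode_frequencies, predict_and_score, reconstruct_signal,
                     region_mode_power)

from conftest import IN_BAND_FREQS, rotation_eigvals


class TestSnapshots:
    def test_definition(self):
        ts = RoiTimeSeries(values=[[1, 2], [2, 4], [4, 8]], dt=1.0)
        pair = build_snapshots(ts)
        np.testing.assert_array_equal(pair.X, [[1, 2], [2, 4]])
        np.testing.assert_array_equal(pair.Xp, [[2, 4], [4, 8]])

    def test_shift_relation_and_shapes(self):
        rng = np.random.default_rng(0)
        ts = RoiTimeSeries(values=rng.normal(size=(140, 300)), dt=2.0)
        pair = build_snapshots(ts)
        assert pair.X.shape == pair.Xp.shape == (300, 139)
        np.testing.assert_array_equal(pair.X[:, 1:], pair.Xp[:, :-1])

    def test_minimal_two_timepoints(self):
        pair = build_snapshots(RoiTimeSeries(values=[[1.0], [2.0]], dt=1.0))
        assert pair.X.shape == (1, 1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            RoiTimeSeries(values=[[1.0, 2.0]], dt=1.0)


class TestExactDmd:
    def test_scalar_decay_eigenvalue(self):
        """x_{k+1} = 0.5 x_k must be recovered as eigenvalue 0.5."""
        x = 0.5 ** np.arange(6)
        dec = DMD(x[:, None], dt=1.0).fit()
        assert dec.n_modes == 1
        np.testing.assert_allclose(dec.eigvals[0], 0.5, atol=1e-10)

    def test_rotation_eigenvalues_and_frequency(self):
        dt = 2.0
        cohort = generate_linear_system_cohort(
            1, R=8, T=60, dt=dt, eigvals=rotation_eigvals(0.05, dt), seed=0)
        dec = DMD(cohort.subjects[0]).fit()
        planted = np.sort_complex(np.asarray(rotation_eigvals(0.05, dt)))
        np.testing.assert_allclose(np.sort_complex(dec.eigvals), planted,
                                   atol=1e-8)
        np.testing.assert_allclose(dec.freqs, 0.05, atol=1e-10)

    def test_planted_eigenvalue_recovery_multimode(self, linear_cohort):
        """Nearest-neighbour matching of recovered to planted eigenvalues."""
        planted = np.asarray(rotation_eigvals(IN_BAND_FREQS))
        for ts in linear_cohort.subjects[:2]:
            dec = DMD(ts).fit()
            assert dec.n_modes == planted.size
            for lam in dec.eigvals:
                assert np.min(np.abs(planted - lam)) < 1e-8

    def test_fullrank_subject_has_T_minus_1_modes(self):
        spec = CohortSpec(n_per_group=1, R=300, T=140, seed=4)
        cohort = generate_sinusoid_cohort(spec)
        dec = DMD(cohort.subjects[0]).fit()
        assert dec.n_modes == 139

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            DMD(np.zeros((10, 3)), dt=1.0).fit()

    def test_rank_cap(self, linear_cohort):
        dec = DMD(linear_cohort.subjects[0]).fit(rank=4)
        assert dec.n_modes == 4
        with pytest.raises(ValueError, match="rank"):
            DMD(linear_cohort.subjects[0]).fit(rank=10_000)

    def test_conjugate_symmetry(self, linear_cohort):
        """Real input: eigenvalues closed under conjugation, paired
        amplitudes equal."""
        dec = DMD(linear_cohort.subjects[0]).fit()
        for i, lam in enumerate(dec.eigvals):
            if abs(lam.imag) < 1e-12:
                continue
            j = int(np.argmin(np.abs(dec.eigvals - np.conj(lam))))
            assert abs(dec.eigvals[j] - np.conj(lam)) < 1e-8
            np.testing.assert_allclose(dec.amplitudes[i], dec.amplitudes[j],
                                       atol=1e-10 * max(1, dec.amplitudes[i]))

    def test_mode_ordering_canonical(self, linear_cohort):
        dec = DMD(linear_cohort.subjects[0]).fit()
        assert np.all(np.diff(dec.freqs) >= -1e-15)


class TestSpectra:
    def test_frequency_examples(self):
        np.testing.assert_allclose(mode_frequencies(np.array([1.0]), 2.0), [0.0])
        lam = np.exp(1j * 0.2 * np.pi)
        np.testing.assert_allclose(
            mode_frequencies(np.array([lam]), 2.0), [0.05], atol=1e-12)
        pair = np.array([lam, np.conj(lam)])
        f = mode_frequencies(pair, 2.0)
        assert f[0] == f[1]

    def test_frequency_bounds_and_nyquist(self):
        rng = np.random.default_rng(1)
        lam = rng.normal(size=20) + 1j * rng.normal(size=20)
        f = mode_frequencies(lam, dt=2.0)
        assert np.all((f >= 0) & (f <= 0.25 + 1e-12))
        np.testing.assert_allclose(
            mode_frequencies(np.array([-0.5 + 0j]), 2.0), [0.25])

    def test_zero_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            mode_frequencies(np.array([0.0 + 0j]), 1.0)

    def test_amplitude_examples(self):
        phi = np.array([[3.0], [4.0j]])
        np.testing.assert_allclose(mode_amplitudes(phi), [25.0])
        assert mode_amplitudes(np.zeros((5, 1)))[0] == 0.0

    def test_amplitude_equals_region_power_sum(self):
        rng = np.random.default_rng(2)
        phi = rng.normal(size=(7, 4)) + 1j * rng.normal(size=(7, 4))
        P = mode_amplitudes(phi)
        Pij = region_mode_power(phi).values
        np.testing.assert_allclose(Pij.sum(axis=1), P, atol=1e-10)


class TestBandFilter:
    def _dec_with_freqs(self, freqs):
        class Stub:
            pass
        from dmdbold.dmd import DmdDecomposition
        n = len(freqs)
        return DmdDecomposition(
            modes=np.ones((2, n), dtype=complex), eigvals=np.ones(n, dtype=complex),
            freqs=np.asarray(freqs, dtype=float), amplitudes=np.ones(n),
            singular_values=np.ones(n), rank=n, dt=2.0)

    def test_keeps_only_in_band(self):
        dec = self._dec_with_freqs([0.005, 0.05, 0.2])
        subset = band_filter_modes(dec, (0.01, 0.1))
        np.testing.assert_array_equal(subset.indices, [1])

    def test_identity_filter(self):
        dec = self._dec_with_freqs([0.0, 0.1, 0.25])
        subset = band_filter_modes(dec, (0.0, 0.25))
        assert len(subset) == 3

    def test_closed_interval_endpoints(self):
        dec = self._dec_with_freqs([0.01, 0.1])
        assert len(band_filter_modes(dec, (0.01, 0.1))) == 2

    def test_empty_band_warns(self):
        dec = self._dec_with_freqs([0.2])
        with pytest.warns(UserWarning, match="no modes"):
            subset = band_filter_modes(dec, (0.01, 0.1))
        assert len(subset) == 0

    def test_conjugate_pairs_kept_together(self, noiseless_sine_cohort):
        dec = DMD(noiseless_sine_cohort.subjects[0]).fit()
        subset = dec.band_subset((0.01, 0.1))
        kept = dec.eigvals[subset.indices]
        non_real = kept[np.abs(kept.imag) > 1e-10]
        assert non_real.size % 2 == 0
        for lam in non_real:
            assert np.min(np.abs(non_real - np.conj(lam))) < 1e-8


class TestReconstruction:
    def test_t0_identity(self, linear_cohort):
        ts = linear_cohort.subjects[0]
        dec = DMD(ts).fit()
        subset = ModeSubset(indices=np.arange(dec.n_modes))
        x0 = ts.values[0]
        np.testing.assert_allclose(
            reconstruct_signal(dec, subset, x0, 0.0), x0, atol=1e-9)

    def test_exact_linear_dynamics_reconstruct_exactly(self, linear_cohort):
        for ts in linear_cohort.subjects:
            dec = DMD(ts).fit()
            times = np.arange(ts.n_timepoints) * ts.dt
            rec = dec.reconstruct_series(ts.values[0], times)
            assert np.max(np.abs(rec - ts.values)) < 1e-8

    def test_noiseless_sine_band_filtered_reconstruction(self, noiseless_sine_cohort):
        """All signal energy is in in-band modes, so the band-filtered
        reconstruction is essentially exact."""
        ts = noiseless_sine_cohort.subjects[0]
        dec = DMD(ts).fit()
        subset = dec.band_subset((0.01, 0.1))
        times = np.arange(ts.n_timepoints) * ts.dt
        rec = dec.reconstruct_series(ts.values[0], times, subset=subset)
        rmse = np.sqrt(np.mean((rec - ts.values) ** 2))
        assert rmse < 1e-6

    def test_empty_subset_rejected(self, linear_cohort):
        dec = DMD(linear_cohort.subjects[0]).fit()
        with pytest.raises(ValueError, match="empty"):
            reconstruct_signal(dec, ModeSubset(indices=np.array([], dtype=int)),
                               linear_cohort.subjects[0].values[0], 0.0)


class TestPrediction:
    def test_exact_linear_extrapolation(self, linear_cohort):
        ts = linear_cohort.subjects[0]
        rmse, flags = predict_and_score(ts, n_train=40)
        assert rmse.shape == (ts.n_timepoints - 40,)
        assert np.all(rmse < 1e-8)
        assert not flags.any()

    def test_horizon_vector_shape(self, linear_cohort):
        ts = linear_cohort.subjects[0]
        rmse, _ = predict_and_score(ts, n_train=ts.n_timepoints - 5)
        assert rmse.shape == (5,)

    def test_invalid_n_train(self, linear_cohort):
        ts = linear_cohort.subjects[0]
        with pytest.raises(ValueError):
            predict_and_score(ts, n_train=ts.n_timepoints)
        with pytest.raises(ValueError):
            predict_and_score(ts, n_train=1)

    def test_outlier_flag(self):
        """A forecast that diverges (unstable fitted eigenvalue) trips the
        RMSE > 1 flag."""
        rng = np.random.default_rng(3)
        values = np.cumsum(rng.normal(size=(60, 3)), axis=0) * 10
        ts = RoiTimeSeries(values=values, dt=2.0)
        rmse, flags = predict_and_score(ts, n_train=20)
        assert flags.dtype == bool and flags.shape == rmse.shape
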