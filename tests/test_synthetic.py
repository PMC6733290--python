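"""Generator ground-truth and reproducibility checks."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from lyoglass import synthetic as syn
from lyoglass.config import C_CM_PER_PS
from lyoglass.reference import REFERENCE_FITS


class TestPiecewiseSeries:
    def test_degenerate_equal_slopes_is_single_line(self, fine_grid_k):
        spec = syn.PiecewiseModelSpec(
            slopes=(0.05, 0.05, 0.05), tb_low_k=200.0, tb_high_k=300.0,
            temperature_k=fine_grid_k, noise_sd_cm=0.0,
        )
        s = syn.simulate_temperature_series(spec)
        fitted = np.polyfit(s.temperature_k, s.absorption_cm, 1)
        assert fitted[0] == pytest.approx(0.05, abs=1e-12)
        residual = s.absorption_cm - np.polyval(fitted, s.temperature_k)
        assert np.max(np.abs(residual)) < 1e-9

    def test_noiseless_series_continuous_at_breakpoints(self, fine_grid_k):
        for ref in REFERENCE_FITS.values():
            spec = syn.PiecewiseModelSpec.from_reference(ref, temperature_k=fine_grid_k)
            for tb in (spec.tb_low_k, spec.tb_high_k):
                below = syn.piecewise_absorption(spec, np.array([tb - 1e-9]))
                above = syn.piecewise_absorption(spec, np.array([tb + 1e-9]))
                assert abs(above[0] - below[0]) < 1e-9

    def test_replicate_sem_matches_brute_force_resampling(self, coarse_grid_k):
        spec = syn.PiecewiseModelSpec(
            slopes=(0.02, 0.06, 0.01), tb_low_k=220.0, tb_high_k=320.0,
            temperature_k=coarse_grid_k, noise_sd_cm=0.1, replicates=3, seed=99,
        )
        s = syn.simulate_temperature_series(spec)
        # brute-force oracle: redo the simulation with the same seed
        rng = np.random.default_rng(99)
        truth = syn.piecewise_absorption(spec, coarse_grid_k)
        draws = truth + rng.normal(0.0, 0.1, size=(3, coarse_grid_k.size))
        np.testing.assert_allclose(s.absorption_cm, draws.mean(axis=0))
        np.testing.assert_allclose(
            s.sd_cm, draws.std(axis=0, ddof=1) / np.sqrt(3)
        )
        # SEM estimates concentrate near sd/sqrt(replicates)
        assert np.mean(s.sd_cm) == pytest.approx(0.1 / np.sqrt(3), rel=0.5)

    def test_breakpoints_outside_grid_rejected(self, coarse_grid_k):
        with pytest.raises(ValueError, match="inside the grid"):
            syn.PiecewiseModelSpec(
                slopes=(0.1, 0.2, 0.3), tb_low_k=50.0, tb_high_k=300.0,
                temperature_k=coarse_grid_k,
            )
        with pytest.raises(ValueError, match="tb_low < tb_high"):
            syn.PiecewiseModelSpec(
                slopes=(0.1, 0.2, 0.3), tb_low_k=320.0, tb_high_k=300.0,
                temperature_k=coarse_grid_k,
            )

    def test_fixed_seed_is_bit_reproducible(self, coarse_grid_k):
        spec = dict(
            slopes=(0.02, 0.06, 0.01), tb_low_k=220.0, tb_high_k=320.0,
            temperature_k=coarse_grid_k, noise_sd_cm=0.05, seed=7,
        )
        a = syn.simulate_temperature_series(syn.PiecewiseModelSpec(**spec))
        b = syn.simulate_temperature_series(syn.PiecewiseModelSpec(**spec))
        assert np.array_equal(a.absorption_cm, b.absorption_cm)
        assert np.array_equal(a.sd_cm, b.sd_cm)


class TestThzPair:
    def test_vacuum_slab_is_identity(self):
        ref, sam = syn.simulate_thz_pair(syn.SlabSpec(thickness_cm=0.05, n=1.0, alpha_cm=0.0))
        np.testing.assert_allclose(sam.amplitude, ref.amplitude, atol=1e-12)

    def test_flat_slab_pure_delay_and_fresnel_amplitude(self):
        # n=1.5, alpha=0: amplitude ratio 4n/(n+1)^2 = 24/25, delay (n-1)d/c
        spec = syn.SlabSpec(thickness_cm=0.05, n=1.5, alpha_cm=0.0)
        ref, sam = syn.simulate_thz_pair(spec)
        delay = 0.5 * 0.05 / C_CM_PER_PS
        # spectral check avoids the sub-sample offset of time-domain peaks
        freq = np.fft.rfftfreq(ref.amplitude.size, d=spec.dt_ps)
        R, S = np.fft.rfft(ref.amplitude), np.fft.rfft(sam.amplitude)
        band = (freq > 0.5) & (freq < 1.5)
        np.testing.assert_allclose(np.abs(S[band] / R[band]), 24 / 25, rtol=1e-9)
        lag = np.argmax(np.correlate(sam.amplitude, ref.amplitude, mode="full")) - (
            ref.amplitude.size - 1
        )
        assert lag == pytest.approx(delay / spec.dt_ps, abs=1.0)

    def test_excessive_delay_raises(self):
        spec = syn.SlabSpec(thickness_cm=5.0, n=3.0, alpha_cm=0.0)
        with pytest.raises(ValueError, match="time window"):
            syn.simulate_thz_pair(spec)

    def test_noise_reproducible_for_seed(self):
        kw = dict(thickness_cm=0.05, n=1.8, alpha_cm=40.0, noise_sd_frac=0.01, seed=3)
        _, a = syn.simulate_thz_pair(syn.SlabSpec(**kw))
        _, b = syn.simulate_thz_pair(syn.SlabSpec(**kw))
        assert np.array_equal(a.amplitude, b.amplitude)


class TestFtirGenerator:
    def test_single_band_closed_form_area(self):
        from lyoglass.ftir import Band

        band = Band(1000.0, 6.0, 2.5, "side-chain")
        s = syn.simulate_ftir([band])
        x = s.wavenumber_cm
        amp = 2.5 / (6.0 * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(
            s.absorbance, amp * np.exp(-((x - 1000.0) ** 2) / 72.0), atol=1e-14
        )
        assert np.trapezoid(s.absorbance, x) == pytest.approx(2.5, rel=1e-6)

    def test_band_table_fraction_bookkeeping(self, amide_grid_cm):
        fr = {"alpha-helix": 0.36, "beta-sheet": 0.34, "turn": 0.20, "random": 0.10}
        bands = syn.amide_band_table(fr)
        assert len(bands) == 10
        for cls, want in fr.items():
            got = sum(b.area for b in bands if b.structure_class == cls)
            assert got == pytest.approx(want, abs=1e-12)
        # mixture area bookkeeping: band areas sum to the integrated spectrum
        s = syn.simulate_ftir(bands, grid_cm=amide_grid_cm)
        total = np.trapezoid(s.absorbance, s.wavenumber_cm)
        assert total == pytest.approx(sum(b.area for b in bands), rel=1e-3)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.amide_band_table({"alpha-helix": 0.5})
        with pytest.raises(ValueError, match="non-empty"):
            syn.simulate_ftir([])


class TestRelaxationGenerator:
    def test_inversion_recovery_limits(self):
        # at t -> 0 with A=1 the magnetisation approaches -M0
        s = syn.simulate_relaxation("T1", m0=2.0, a=1.0, t_s=0.8,
                                    delays_s=np.array([1e-9, 0.1, 0.5, 5.0]))
        assert s.magnetisation[0] == pytest.approx(-2.0, rel=1e-6)

    def test_spin_lock_closed_form_at_t1rho(self):
        t1rho = 0.01
        s = syn.simulate_relaxation(
            "T1rho", m0=1.0, t_s=t1rho, delays_s=np.array([1e-6, t1rho, 0.02, 0.05])
        )
        assert s.magnetisation[1] == pytest.approx(1.0 / np.e, rel=1e-9)

    def test_default_grids_are_the_standard_eight_points(self):
        t1 = syn.simulate_relaxation("T1")
        t1r = syn.simulate_relaxation("T1rho")
        np.testing.assert_allclose(t1.delays_s, [0.01, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0])
        np.testing.assert_allclose(
            t1r.delays_s, np.array([0.1, 1, 5, 10, 20, 30, 40, 50]) * 1e-3
        )

    def test_nonpositive_relaxation_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.simulate_relaxation("T1", t_s=0.0)


class TestCdGenerator:
    def test_helix_basis_band_positions(self):
        s = syn.simulate_cd({"helix": 1.0})
        wl, y = s.wavelength_nm, s.theta_obs_mdeg
        assert y[wl == 193.0][0] > 0
        mins = wl[np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1]
        assert np.any(np.abs(mins - 208.0) <= 1.0)
        assert np.any(np.abs(mins - 222.0) <= 1.0)

    def test_sheet_basis_single_minimum_at_218(self):
        s = syn.simulate_cd({"sheet": 1.0})
        wl, y = s.wavelength_nm, s.theta_obs_mdeg
        mins = wl[np.flatnonzero((y[1:-1] < y[:-2]) & (y[1:-1] <= y[2:])) + 1]
        deep = [m for m in mins if y[wl == m][0] < 0]
        assert len(deep) == 1
        assert abs(deep[0] - 218.0) <= 1.0

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            syn.simulate_cd({"helix": 1.5, "sheet": -0.5})
        with pytest.raises(ValueError, match="sum to 1"):
            syn.simulate_cd({"helix": 0.4})


@given(seed=st.integers(0, 2**31 - 1))
def test_all_generators_reproducible_for_any_seed(seed):
    """Equal seeds give bit-identical stochastic output across modalities."""
    kw = dict(
        slopes=(0.02, 0.05, 0.01), tb_low_k=200.0, tb_high_k=300.0,
        temperature_k=np.arange(100.0, 381.0, 10.0), noise_sd_cm=0.05, seed=seed,
    )
    a = syn.simulate_temperature_series(syn.PiecewiseModelSpec(**kw))
    b = syn.simulate_temperature_series(syn.PiecewiseModelSpec(**kw))
    assert np.array_equal(a.absorption_cm, b.absorption_cm)
    ca = syn.simulate_cd({"helix": 1.0}, noise_sd=0.5, seed=seed)
    cb = syn.simulate_cd({"helix": 1.0}, noise_sd=0.5, seed=seed)
    assert np.array_equal(ca.theta_obs_mdeg, cb.theta_obs_mdeg)
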