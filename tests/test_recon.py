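import numpy as np
import pytest

from adipoquant.recon import (
    EchoSeries,
    ReconConfig,
    coil_combine,
    estimate_fieldmap,
    estimate_r2star,
    reconstruct,
    solve_fat_water,
)
from adipoquant.signal_model import (
    EchoTimes,
    FatSpectrum,
    VoxelSignalParams,
    default_echo_times,
    default_fat_spectrum,
    simulate_signal_maps,
    simulate_voxel_signal,
)
from adipoquant.synthetic import PhantomSpec, make_phantom

TES = default_echo_times(6)
SPECTRUM = default_fat_spectrum(3.0)


def uniform_series(W, F, psi, r2, shape=(8, 8, 2), tes=TES):
    sig = simulate_signal_maps(
        np.full(shape, W), np.full(shape, F), np.full(shape, psi),
        np.full(shape, r2), tes, SPECTRUM)
    return EchoSeries(sig, tes)


class TestCoilCombine:
    def test_single_coil_passthrough(self):
        series = uniform_series(1, 0, 0, 0)
        out = coil_combine(series)
        np.testing.assert_array_equal(out.data, series.data)

    def test_two_coils_recover_truth_image(self):
        """Oracle: the truth image up to a global complex scale."""
        spec = PhantomSpec(shape=(24, 24, 2), snr=None, seed=3)
        truth_series = make_phantom(spec)[2]
        _, truth_seg, series2 = make_phantom(
            PhantomSpec(shape=(24, 24, 2), snr=None, seed=3, n_coils=2))
        comb = coil_combine(series2)
        fg = truth_seg.labels > 0
        mag_c = np.abs(comb.data)[fg]
        mag_t = np.abs(truth_series.data)[fg]
        assert np.max(np.abs(mag_c - mag_t) / mag_t) < 0.01
        # inter-echo phase of the combination matches the truth
        ph_c = np.angle(comb.data[fg][:, 1] / comb.data[fg][:, 0])
        ph_t = np.angle(truth_series.data[fg][:, 1] / truth_series.data[fg][:, 0])
        assert np.max(np.abs(ph_c - ph_t)) < 0.01


class TestFieldmap:
    def test_zero_field_recovered(self):
        series = uniform_series(0.6, 0.4, 0.0, 0.0)
        psi = estimate_fieldmap(series)
        assert np.max(np.abs(psi)) < 0.1

    def test_constant_offset_matches_grid_search_oracle(self):
        """Oracle: dense 1-D grid over psi minimizing the fit residual of a
        single voxel, independent of the production solver."""
        p = VoxelSignalParams(W=0.55, F=0.45, psi=30.0, r2star=0.0)
        s = simulate_voxel_signal(p, TES, SPECTRUM)
        t = TES.seconds
        c = SPECTRUM.modulation(t)
        grid = np.linspace(-100, 100, 80001)
        best, best_rss = None, np.inf
        A0 = np.column_stack([np.ones(6), c])
        for psi in grid:
            y = s * np.exp(-2j * np.pi * psi * t)
            x, rss, *_ = np.linalg.lstsq(A0, y, rcond=None)
            r = float(np.abs(y - A0 @ x).sum()) if rss.size == 0 else float(rss[0].real)
            if r < best_rss:
                best, best_rss = psi, r
        assert best == pytest.approx(30.0, abs=0.05)
        series = uniform_series(0.55, 0.45, 30.0, 0.0)
        psi_map = estimate_fieldmap(series)
        assert np.max(np.abs(psi_map - 30.0)) < 0.1

    def test_linear_ramp_no_swaps(self):
        # decay-free truth isolates the field-mapping stage (the joint
        # psi/R2* refinement inside reconstruct() handles decaying tissue)
        spec = PhantomSpec(shape=(32, 32, 2), snr=None, seed=0,
                           fieldmap_model="ramp", fieldmap_amplitude_hz=50.0,
                           r2star={"BMAT": 0.0, "MUS": 0.0, "SAT": 0.0})
        truth_maps, truth_seg, series = make_phantom(spec)
        psi = estimate_fieldmap(series)
        fg = truth_seg.labels > 0
        assert np.max(np.abs(psi - truth_maps.fieldmap)[fg]) < 1.0


class TestFatWaterSolve:
    def test_water_only(self):
        series = uniform_series(1, 0, 0, 0)
        W, F, _ = solve_fat_water(series, psi=0.0)
        assert np.max(F / (W + F)) < 1e-6

    def test_fat_only(self):
        series = uniform_series(0, 1, 0, 0)
        W, F, _ = solve_fat_water(series, psi=0.0)
        assert np.min(F / (W + F)) > 1 - 1e-6

    def test_half_half_matches_normal_equations_oracle(self):
        """Oracle: direct normal-equations solve with known psi and R2*."""
        p = VoxelSignalParams(W=0.5, F=0.5, psi=12.0, r2star=30.0)
        s = simulate_voxel_signal(p, TES, SPECTRUM)
        t = TES.seconds
        y = s * np.exp((-2j * np.pi * p.psi + p.r2star) * t)
        A = np.column_stack([np.ones(6), SPECTRUM.modulation(t)])
        x = np.linalg.solve(A.conj().T @ A, A.conj().T @ y)
        oracle_pdff = abs(x[1]) / (abs(x[0]) + abs(x[1]))
        series = uniform_series(0.5, 0.5, 12.0, 30.0)
        W, F, _ = solve_fat_water(series, psi=12.0, r2star=30.0)
        pdff = F / (W + F)
        assert np.max(np.abs(pdff - 0.5)) < 1e-9
        assert oracle_pdff == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_spectrum_rejected(self):
        series = uniform_series(1, 0, 0, 0)
        flat = FatSpectrum(peaks=((0.0, 1.0),), field_strength=3.0)
        with pytest.raises(ValueError, match="echo-time pattern"):
            solve_fat_water(series, psi=0.0, spectrum=flat)


class TestR2star:
    def test_known_decay_recovered(self):
        series = uniform_series(0.6, 0.4, 10.0, 40.0, shape=(6, 6, 1))
        r2 = estimate_r2star(series, psi=np.full((6, 6, 1), 10.0))
        assert np.max(np.abs(r2 - 40.0)) < 0.4

    def test_zero_decay(self):
        series = uniform_series(0.6, 0.4, 0.0, 0.0, shape=(6, 6, 1))
        r2 = estimate_r2star(series, psi=np.zeros((6, 6, 1)))
        assert np.max(r2) < 1.0

    def test_doubling_truth_doubles_estimate(self):
        est = []
        for r in (30.0, 60.0):
            series = uniform_series(0.5, 0.5, 0.0, r, shape=(4, 4, 1))
            r2 = estimate_r2star(series, psi=np.zeros((4, 4, 1)))
            est.append(np.median(r2))
        assert est[1] / est[0] == pytest.approx(2.0, rel=0.02)

    def test_three_echo_falls_back_to_prior(self):
        series = uniform_series(0.5, 0.5, 0.0, 40.0, tes=default_echo_times(3))
        with pytest.warns(UserWarning, match="marginally"):
            r2 = estimate_r2star(series, psi=np.zeros(series.data.shape[:3]))
        np.testing.assert_array_equal(r2, 0.0)


class TestReconstruct:
    def test_noiseless_recovery(self, small_noiseless_phantom):
        truth_maps, truth_seg, series = small_noiseless_phantom
        maps = reconstruct(series)
        fg = (truth_seg.labels > 0) & maps.valid
        assert np.max(np.abs(maps.pdff - truth_maps.pdff)[fg]) < 1e-3
        assert np.max(np.abs(maps.fieldmap - truth_maps.fieldmap)[fg]) < 1.0
        rel = np.abs(maps.r2star - truth_maps.r2star)[fg] / truth_maps.r2star[fg]
        assert np.max(rel) < 0.01

    def test_noisy_recovery_and_no_swaps(self, small_noisy_phantom):
        truth_maps, truth_seg, series = small_noisy_phantom
        maps = reconstruct(series)
        fg = (truth_seg.labels > 0) & maps.valid
        err = np.abs(maps.pdff - truth_maps.pdff)[fg]
        assert np.median(err) < 0.02
        assert int((err > 0.5).sum()) == 0

    def test_echo_permutation_invariance(self):
        series = uniform_series(0.4, 0.6, 20.0, 50.0, shape=(6, 6, 1))
        perm = np.array([3, 0, 5, 1, 4, 2])
        # metadata must stay sorted: permute data then invert via matching TEs
        tes_p = tuple(np.array(TES.values_ms)[perm])
        order = np.argsort(tes_p)
        series_p = EchoSeries(
            series.data[..., perm][..., order],
            EchoTimes(tuple(np.sort(tes_p))),
        )
        a = reconstruct(series, ReconConfig(estimate_r2star=False))
        b = reconstruct(series_p, ReconConfig(estimate_r2star=False))
        np.testing.assert_allclose(a.pdff, b.pdff, atol=1e-9)

    def test_global_complex_scale_invariance(self):
        series = uniform_series(0.4, 0.6, 15.0, 30.0, shape=(6, 6, 1))
        scaled = EchoSeries(series.data * (1.7 * np.exp(0.9j)), TES)
        a = reconstruct(series)
        b = reconstruct(scaled)
        np.testing.assert_allclose(a.pdff, b.pdff, atol=1e-7)

    def test_three_echo_mode_recorded(self):
        series = uniform_series(0.5, 0.5, 0.0, 0.0, tes=default_echo_times(3))
        with pytest.warns(UserWarning, match="3-echo"):
            maps = reconstruct(series)
        assert maps.meta["joint_r2star"] is False
        fg = maps.valid
        assert np.max(np.abs(maps.pdff[fg] - 0.5)) < 1e-3

    def test_mismatched_echo_axis_rejected(self):
        with pytest.raises(ValueError, match="echo axis"):
            EchoSeries(np.zeros((4, 4, 1, 5), complex), TES)
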