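"""2D pipeline tests: fixture generation, transforms, nmrPipe I/O,
slice-wise reconstruction."""

import numpy as np
import pytest

from nusnet import fid_model, reconstruction, schedules
from nusnet.fid_model import AxisMeta
from nusnet.reconstruction import (
    DnnModel,
    IstModel,
    Peak2D,
    Spectrum2D,
    ZeroFillModel,
    apply_indirect_window,
    bin_to_ppm,
    ft_direct,
    ft_indirect,
    make_fixture_2d,
    ppm_to_bin,
    read_nmrpipe,
    reconstruct_slices,
    squaresine_window,
    write_nmrpipe,
)
from nusnet.baseline_ist import IstConfig


class TestAxisConversions:
    def test_ppm_bin_involutive(self, fixture_axes):
        direct, indirect = fixture_axes
        for axis in (direct, indirect):
            bins = np.arange(axis.n_points, dtype=float)
            np.testing.assert_allclose(
                ppm_to_bin(axis, bin_to_ppm(axis, bins)), bins, atol=1e-9)

    def test_ppm_decreases_with_bin_index(self, fixture_axes):
        direct, _ = fixture_axes
        ppm = bin_to_ppm(direct, np.arange(direct.n_points))
        assert np.all(np.diff(ppm) < 0)

    def test_carrier_at_window_centre(self, fixture_axes):
        _, indirect = fixture_axes
        centre = bin_to_ppm(indirect, indirect.n_points / 2.0 - 1.0)
        assert centre == pytest.approx(indirect.carrier)


class TestFixture:
    def test_single_peak_lands_on_expected_bins(self, fixture_axes):
        """DFT oracle: one on-grid peak, no noise — after both FTs the
        maximum sits at the bins nearest the requested ppm position."""
        direct, indirect = fixture_axes
        peak = Peak2D(ppm_h=8.2, ppm_n=120.0, intensity=1.0, r2_h=15.0,
                      r2_n=8.0)
        spec = make_fixture_2d([peak], direct, indirect)
        final = ft_indirect(apply_indirect_window(ft_direct(spec)))
        ih, in_ = np.unravel_index(np.argmax(final.data), final.data.shape)
        assert ih == int(round(float(ppm_to_bin(direct, 8.2))))
        assert in_ == int(round(float(ppm_to_bin(indirect, 120.0))))

    def test_energy_concentrated_near_peak(self, fixture_axes):
        """>= 95% of spectral energy within +-2 bins of the expected
        position for a noise-free single-peak fixture."""
        direct, indirect = fixture_axes
        # r2_h large enough that the 10.7 ms direct acquisition captures
        # most of the decay; truncation wings otherwise dominate the tails
        peak = Peak2D(ppm_h=9.0, ppm_n=115.0, intensity=1.0, r2_h=100.0,
                      r2_n=20.0)
        spec = make_fixture_2d([peak], direct, indirect)
        final = ft_indirect(apply_indirect_window(ft_direct(spec)))
        power = final.data ** 2
        ih, in_ = np.unravel_index(np.argmax(power), power.shape)
        window = power[max(ih - 2, 0):ih + 3, max(in_ - 2, 0):in_ + 3]
        assert window.sum() / power.sum() >= 0.95

    def test_zero_peaks_pure_noise_sd(self, fixture_axes):
        direct, indirect = fixture_axes
        spec = make_fixture_2d([], direct, indirect, noise_sigma=0.3, seed=4)
        assert np.std(spec.data.real) == pytest.approx(0.3, rel=0.05)
        assert np.std(spec.data.imag) == pytest.approx(0.3, rel=0.05)

    def test_same_seed_identical(self, fixture_axes):
        direct, indirect = fixture_axes
        a = make_fixture_2d(reconstruction.hsqc_like_peaks(), direct,
                            indirect, noise_sigma=0.1, seed=7)
        b = make_fixture_2d(reconstruction.hsqc_like_peaks(), direct,
                            indirect, noise_sigma=0.1, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_default_peaks_cover_both_nitrogen_regions(self):
        peaks = reconstruction.hsqc_like_peaks()
        ns = [p.ppm_n for p in peaks]
        assert any(105 <= n <= 130 for n in ns)  # amide region
        assert any(82 <= n <= 88 for n in ns)  # arginine epsilon region
        r2s = [p.r2_n for p in peaks]
        assert max(r2s) / min(r2s) > 5  # sharp and broad lines


class TestTransforms:
    def test_domain_flags_track_transforms(self, hsqc_fixture):
        s1 = ft_direct(hsqc_fixture)
        assert (s1.direct_domain, s1.indirect_domain) == ("freq", "time")
        s2 = apply_indirect_window(s1)
        s3 = ft_indirect(s2)
        assert (s3.direct_domain, s3.indirect_domain) == ("freq", "freq")

    def test_time_domain_ops_refuse_frequency_data(self, hsqc_fixture):
        s = ft_direct(hsqc_fixture)
        with pytest.raises(ValueError):
            ft_direct_twice = ft_direct(s)  # noqa: F841
        final = ft_indirect(apply_indirect_window(s))
        with pytest.raises(ValueError):
            apply_indirect_window(final)
        with pytest.raises(ValueError):
            ft_indirect(final)

    def test_single_frequency_row_gives_single_dominant_bin(self):
        axis = AxisMeta(sw=1000.0, n_points=64, obs=100.0, carrier=0.0)
        other = AxisMeta(sw=1000.0, n_points=4, obs=100.0, carrier=0.0)
        t = np.arange(64) / 1000.0
        row = np.exp(1j * 2 * np.pi * 250.0 * t)
        data = np.zeros((64, 2, 4), dtype=complex)
        data[:, 0, 0] = row
        spec = ft_direct(Spectrum2D(data=data, direct=axis, indirect=other))
        mags = np.abs(spec.data[:, 0])
        assert mags.max() > 10 * np.sort(mags)[-2]  # one dominant bin

    def test_parseval_energy_conserved(self):
        """Unitary-FT check (no first-point halving on a signal whose
        first point is zero)."""
        rng = np.random.default_rng(0)
        axis = AxisMeta(sw=1000.0, n_points=32, obs=100.0, carrier=0.0)
        x = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        x[0] = 0.0  # first-point scaling has no effect
        X = reconstruction._ft1d(x, axis=0)
        assert np.sum(np.abs(X) ** 2) == pytest.approx(
            32 * np.sum(np.abs(x) ** 2), rel=1e-12)


class TestWindow:
    def test_first_point_closed_form(self):
        w = squaresine_window(64)
        assert w[0] == pytest.approx(np.sin(0.42 * np.pi) ** 2, rel=1e-12)

    def test_last_point_is_zero(self):
        w = squaresine_window(64)
        assert w[-1] == pytest.approx(0.0, abs=1e-30)

    def test_all_values_in_unit_interval(self):
        w = squaresine_window(256)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)

    def test_matches_stated_formula_everywhere(self):
        n = 32
        j = np.arange(n)
        expect = np.sin(np.pi * (0.42 + (1.0 - 0.42) * j / (n - 1))) ** 2
        np.testing.assert_allclose(squaresine_window(n), expect, rtol=1e-12)


class TestNmrPipeIO:
    def test_time_time_round_trip(self, hsqc_fixture, tmp_path):
        path = tmp_path / "fix.fid"
        write_nmrpipe(hsqc_fixture, path)
        back = read_nmrpipe(path)
        # single-precision storage
        np.testing.assert_allclose(back.data, hsqc_fixture.data,
                                   atol=2e-6 * np.abs(hsqc_fixture.data).max())
        assert back.direct.sw == pytest.approx(12000.0)
        assert back.indirect.sw == pytest.approx(5100.0)
        assert (back.direct_domain, back.indirect_domain) == ("time", "time")

    def test_interferogram_round_trip(self, hsqc_fixture, tmp_path):
        spec = ft_direct(hsqc_fixture)
        path = tmp_path / "fix.ft1"
        write_nmrpipe(spec, path)
        back = read_nmrpipe(path)
        np.testing.assert_allclose(back.data, spec.data,
                                   atol=5e-6 * np.abs(spec.data).max())
        assert (back.direct_domain, back.indirect_domain) == ("freq", "time")

    def test_spectrum_round_trip(self, full_processed, tmp_path):
        path = tmp_path / "fix.ft2"
        write_nmrpipe(full_processed, path)
        back = read_nmrpipe(path)
        np.testing.assert_allclose(
            back.data, full_processed.data,
            atol=5e-6 * np.abs(full_processed.data).max())
        assert back.direct.carrier == pytest.approx(4.77, abs=1e-5)
        assert back.indirect.obs == pytest.approx(70.95, abs=1e-4)

    def test_truncated_file_clean_error(self, hsqc_fixture, tmp_path):
        path = tmp_path / "fix.fid"
        write_nmrpipe(hsqc_fixture, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="truncated"):
            read_nmrpipe(path)

    def test_short_header_clean_error(self, tmp_path):
        path = tmp_path / "bad.fid"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(ValueError, match="header"):
            read_nmrpipe(path)


class TestReconstructSlices:
    def test_identity_with_full_schedule_and_stub_model(
            self, hsqc_fixture, full_schedule_64):
        """Pipeline plumbing: a full schedule plus the zero-fill stub
        reproduces the conventionally processed spectrum bit-for-bit."""
        after_direct = ft_direct(hsqc_fixture)
        rec = reconstruct_slices(after_direct, full_schedule_64,
                                 ZeroFillModel(full_schedule_64))
        np.testing.assert_array_equal(rec.data, after_direct.data)
        final_rec = ft_indirect(apply_indirect_window(rec))
        final_full = ft_indirect(apply_indirect_window(after_direct))
        np.testing.assert_array_equal(final_rec.data, final_full.data)

    def test_all_zero_slice_stays_zero(self, fixture_axes, sched_64_16,
                                       trained_model_64):
        """Noise-free empty slices take the guard path and come back
        exactly zero instead of being normalised and amplified."""
        direct, indirect = fixture_axes
        params, _, _ = trained_model_64
        rng = np.random.default_rng(0)
        t = np.arange(64) * indirect.dt
        data = np.zeros((8, 64), dtype=complex)
        for row in (1, 4):  # two signal-bearing slices, six empty ones
            nu = rng.uniform(-2000, 2000)
            data[row] = np.exp((1j * 2 * np.pi * nu - 12.0) * t)
        interferogram = Spectrum2D(data=data, direct=AxisMeta(
            sw=12000.0, n_points=8, obs=700.0, carrier=4.77),
            indirect=indirect, direct_domain="freq", indirect_domain="time")
        rec = reconstruct_slices(interferogram, sched_64_16,
                                 DnnModel(params, sched_64_16))
        dead = np.ones(8, dtype=bool)
        dead[[1, 4]] = False
        np.testing.assert_array_equal(rec.data[dead], 0.0)
        assert np.all(np.abs(rec.data[[1, 4]]).max(axis=1) > 0.5)

    def test_trained_model_beats_zero_fill_per_slice(
            self, hsqc_fixture, sched_64_16, trained_model_64):
        """Per-slice frequency-domain RMSD of the learned reconstruction
        is below the zero-fill baseline for >= 80% of signal-bearing
        slices of the HSQC-like fixture."""
        params, _, _ = trained_model_64
        after_direct = ft_direct(hsqc_fixture)
        full = ft_indirect(apply_indirect_window(after_direct))

        def pipeline(model):
            rec = reconstruct_slices(after_direct, sched_64_16, model)
            return ft_indirect(apply_indirect_window(rec))

        rec_dnn = pipeline(DnnModel(params, sched_64_16))
        rec_zf = pipeline(ZeroFillModel(sched_64_16))
        first_mag = np.abs(after_direct.data[:, 0])
        live = first_mag > 0.01 * first_mag.max()
        rmsd_dnn = np.sqrt(np.mean(
            (rec_dnn.data[live] - full.data[live]) ** 2, axis=1))
        rmsd_zf = np.sqrt(np.mean(
            (rec_zf.data[live] - full.data[live]) ** 2, axis=1))
        assert np.mean(rmsd_dnn < rmsd_zf) >= 0.80

    def test_ist_model_through_pipeline(self, hsqc_fixture, sched_64_16):
        """The IST baseline through the same pipeline recovers the
        strongest fixture peak at its true position."""
        after_direct = ft_direct(hsqc_fixture)
        full = ft_indirect(apply_indirect_window(after_direct))
        rec = reconstruct_slices(
            after_direct, sched_64_16,
            IstModel(sched_64_16, IstConfig(iterations=200)))
        final = ft_indirect(apply_indirect_window(rec))
        assert np.unravel_index(np.argmax(final.data), final.data.shape) == \
            np.unravel_index(np.argmax(full.data), full.data.shape)

    def test_model_schedule_mismatch_rejected(self, trained_model_64,
                                              hsqc_fixture):
        params, _, _ = trained_model_64
        other = schedules.poisson_gap_schedule(64, 20, seed=0)
        with pytest.raises(ValueError):
            DnnModel(params, other)
        after_direct = ft_direct(hsqc_fixture)
        sched16 = schedules.poisson_gap_schedule(64, 16, seed=5)
        model = ZeroFillModel(schedules.poisson_gap_schedule(64, 20, seed=1))
        with pytest.raises(ValueError):
            reconstruct_slices(after_direct, sched16, model)


class TestDnnModelGuard:
    def test_loaded_model_refuses_mismatched_grid(self, trained_model_64,
                                                  tmp_path):
        from nusnet import network
        params, _, cfg = trained_model_64
        path = tmp_path / "m.npz"
        network.save_params(params, path, schedule=cfg.schedule)
        with pytest.raises(ValueError):
            network.load_params(path, expect_n_points=128)
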