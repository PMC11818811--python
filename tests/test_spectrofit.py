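"""Variable-projection titration fitting: round-trips, identifiability,
spectral properties."""

import numpy as np
import pytest

from calixtherm import spectrofit, synthgen
from calixtherm.equilibria import TitrationSeries, speciation_profile
from calixtherm.spectrofit import (
    UnidentifiableError,
    dilution_correct,
    fit_competitive,
    fit_direct,
    subtract_blank_overlap,
)
from calixtherm.synthgen import make_1to1_model, make_competitive_model


def noise_level(dataset, fraction):
    return fraction * float(np.abs(dataset.responses).max())


def constant_ligand_series(c_l=1e-4, ratios=np.linspace(0.05, 2.0, 20)):
    """Series with constant ligand total (dilution-corrected data model)."""
    totals = np.column_stack([np.full_like(ratios, c_l), ratios * c_l])
    return TitrationSeries(["L", "M"], totals, np.arange(1.0, len(ratios) + 1.0), 2.2)


class TestDilutionCorrect:
    def test_single_point_arithmetic(self, uv_protocol):
        ds, _ = synthgen.gen_titration_spectra(make_1to1_model(5.0), uv_protocol, 0.0)
        raw = ds.responses.copy()
        ds.dilution_corrected = False  # treat the simulated matrix as raw
        corr = dilution_correct(ds)
        i = np.argmin(np.abs(uv_protocol.volumes - 0.22))
        factor = (2.2 + uv_protocol.volumes[i]) / 2.2
        np.testing.assert_allclose(corr.responses[i], raw[i] * factor, rtol=1e-14)

    def test_zero_added_volume_unchanged(self):
        series = TitrationSeries(["L"], [[1e-4]], [0.0], 2.2)
        ds = spectrofit.SpectralDataset(
            "absorbance", np.array([350.0, 360.0]), np.array([[0.5, 0.6]]), series
        )
        corr = dilution_correct(ds)
        np.testing.assert_allclose(corr.responses, ds.responses)

    def test_round_trip_and_double_correction_guard(self, uv_protocol):
        rng = np.random.default_rng(0)
        n = uv_protocol.n_points
        ds = spectrofit.SpectralDataset(
            "absorbance", np.arange(300.0, 310.0), rng.uniform(0, 1, (n, 10)), uv_protocol
        )
        corr = dilution_correct(ds)
        factors = (2.2 + uv_protocol.volumes) / 2.2
        np.testing.assert_allclose(corr.responses / factors[:, None], ds.responses, atol=1e-15)
        with pytest.raises(ValueError, match="already"):
            dilution_correct(corr)


class TestFitDirect:
    def test_noiseless_recovery_to_millilog(self, uv_protocol):
        model = make_1to1_model(5.0)
        ds, _ = synthgen.gen_titration_spectra(model, uv_protocol, 0.0)
        fit = fit_direct(ds, model.with_log_beta("ML", 4.0))
        assert fit.log_betas["ML"] == pytest.approx(5.000, abs=1e-3)
        assert not fit.unidentifiable

    @pytest.mark.parametrize("truth", [2.8, 3.5, 5.0])
    def test_noisy_recovery_within_reported_tolerance(self, truth):
        series = synthgen.default_uv_protocol(c_titrant=1.31e-2, max_ratio=30, n_points=20)
        model = make_1to1_model(truth)
        clean, _ = synthgen.gen_titration_spectra(model, series, 0.0)
        ds, _ = synthgen.gen_titration_spectra(
            model, series, noise_sd=noise_level(clean, 0.002), seed=42
        )
        fit = fit_direct(ds, model.with_log_beta("ML", 4.0))
        assert fit.log_betas["ML"] == pytest.approx(truth, abs=0.05)

    def test_round_trip_bias_below_reported_se(self):
        # median |bias| over a grid of truths stays below the reported SE
        biases, ses = [], []
        for i, truth in enumerate([2.0, 3.0, 4.0, 5.0, 6.0]):
            series = synthgen.default_uv_protocol(c_titrant=1.31e-2, max_ratio=40, n_points=18)
            model = make_1to1_model(truth)
            clean, _ = synthgen.gen_titration_spectra(model, series, 0.0)
            ds, _ = synthgen.gen_titration_spectra(
                model, series, noise_sd=noise_level(clean, 0.002), seed=100 + i
            )
            fit = fit_direct(ds, model.with_log_beta("ML", 4.5))
            biases.append(abs(fit.log_betas["ML"] - truth))
            ses.append(fit.std_errors["ML"])
        assert np.median(biases) < np.median(ses) * 3

    def test_steep_isotherm_flagged_unidentifiable(self, uv_protocol):
        model = make_1to1_model(11.0)
        clean, _ = synthgen.gen_titration_spectra(model, uv_protocol, 0.0)
        ds, _ = synthgen.gen_titration_spectra(
            model, uv_protocol, noise_sd=noise_level(clean, 0.002), seed=3
        )
        fit = fit_direct(ds, model.with_log_beta("ML", 9.0))
        assert fit.unidentifiable
        assert fit.std_errors["ML"] > 1.0

    def test_ligand_only_data_rejected(self):
        series = TitrationSeries(
            ["L", "M"], np.column_stack([np.full(5, 1e-4), np.zeros(5)]),
            np.arange(5.0), 2.2,
        )
        model = make_1to1_model(5.0)
        ds, _ = synthgen.gen_titration_spectra(model, series, 0.0)
        with pytest.raises(UnidentifiableError):
            fit_direct(ds, model)


@pytest.fixture(scope="module")
def competitive_data(competitive_protocol):
    model = make_competitive_model(11.65)
    clean, _ = synthgen.gen_titration_spectra(model, competitive_protocol, 0.0)
    ds, _ = synthgen.gen_titration_spectra(
        model, competitive_protocol, noise_sd=noise_level(clean, 0.003), seed=11
    )
    return ds


class TestFitCompetitive:
    def test_displacement_recovers_high_constant(self, competitive_data):
        model = make_competitive_model(11.65)
        fit = fit_competitive(competitive_data, model.with_log_beta("ML", 11.0))
        assert fit.log_betas["ML"] == pytest.approx(11.65, abs=0.1)
        assert not fit.unidentifiable

    def test_reference_misspecification_shifts_estimate(self, competitive_data):
        # a +0.1 error in the fixed reference biases the result by ~+0.1
        good = fit_competitive(competitive_data, make_competitive_model(11.0))
        off = fit_competitive(competitive_data, make_competitive_model(11.0, log_k_ref=10.60))
        assert off.log_betas["ML"] - good.log_betas["ML"] == pytest.approx(0.1, abs=0.03)

    def test_weak_competitor_inflates_uncertainty(self, competitive_protocol):
        # far below the reference the displacement signal vanishes; the
        # profile-based SE grows by an order of magnitude and eventually
        # triggers the identifiability flag
        ses = {}
        for truth, seed in [(11.65, 11), (8.5, 5), (7.5, 5)]:
            model = make_competitive_model(truth)
            clean, _ = synthgen.gen_titration_spectra(model, competitive_protocol, 0.0)
            ds, _ = synthgen.gen_titration_spectra(
                model, competitive_protocol, noise_sd=noise_level(clean, 0.003), seed=seed
            )
            fit = fit_competitive(ds, model.with_log_beta("ML", 9.5))
            ses[truth] = (fit.std_errors["ML"], fit.unidentifiable)
        assert ses[8.5][0] > 10 * ses[11.65][0]
        assert ses[7.5][1]  # no displacement information left

    def test_requires_fixed_reference_and_competing_titrant(self, competitive_data):
        model = make_competitive_model(11.65)
        unfixed = type(model)(
            model.components,
            [type(sp)(sp.name, dict(sp.stoich), sp.log_beta, False) for sp in model.species],
        )
        with pytest.raises(ValueError, match="fixed reference"):
            fit_competitive(competitive_data, unfixed)


class TestBlankSubtraction:
    def grid(self):
        return np.arange(340.0, 420.0, 2.0)

    def test_blank_equal_to_data_zeroes_spectra(self):
        wl = self.grid()
        series = TitrationSeries(["L"], np.full((3, 1), 1e-4), np.arange(3.0), 2.5)
        blank = np.exp(-0.5 * ((wl - 360) / 8.0) ** 2)
        ds = spectrofit.SpectralDataset(
            "fluorescence", wl, np.vstack([blank, 2 * blank, 0.5 * blank]), series
        )
        out = subtract_blank_overlap(ds, blank)
        np.testing.assert_allclose(out.responses, 0.0, atol=1e-12)

    def test_zero_blank_is_identity(self):
        wl = self.grid()
        series = TitrationSeries(["L"], np.full((2, 1), 1e-4), np.arange(2.0), 2.5)
        rng = np.random.default_rng(1)
        ds = spectrofit.SpectralDataset(
            "fluorescence", wl, rng.uniform(0, 1, (2, len(wl))), series
        )
        out = subtract_blank_overlap(ds, np.zeros_like(wl))
        np.testing.assert_allclose(out.responses, ds.responses)

    def test_scaled_overlap_band_removed_within_noise(self):
        wl = self.grid()
        rng = np.random.default_rng(7)
        emission = 10.0 * np.exp(-0.5 * ((wl - 390) / 10.0) ** 2)
        overlap = np.exp(-0.5 * ((wl - 350) / 5.0) ** 2)
        noise = 0.01
        scales = np.array([0.8, 1.3, 2.1])
        resp = emission[None, :] + np.outer(scales, overlap) + rng.normal(0, noise, (3, len(wl)))
        series = TitrationSeries(["L"], np.full((3, 1), 1e-4), np.arange(3.0), 2.5)
        ds = spectrofit.SpectralDataset("fluorescence", wl, resp, series)
        out = subtract_blank_overlap(ds, overlap, window=(340.0, 362.0))
        in_window = (wl >= 340) & (wl <= 362)
        residual = out.responses[:, in_window] - emission[in_window]
        assert np.abs(residual).max() < 5 * noise

    def test_grid_mismatch_rejected(self):
        wl = self.grid()
        series = TitrationSeries(["L"], np.full((1, 1), 1e-4), [0.0], 2.5)
        ds = spectrofit.SpectralDataset("fluorescence", wl, np.ones((1, len(wl))), series)
        with pytest.raises(ValueError, match="grid"):
            subtract_blank_overlap(ds, np.ones(len(wl) + 3))


class TestSpectralProperties:
    def test_isosbestic_points_in_noiseless_1to1_titration(self):
        # where the free and complexed ligand have equal molar absorbance,
        # all dilution-corrected spectra must intersect
        series = constant_ligand_series()
        model = make_1to1_model(6.0)
        ds, truth = synthgen.gen_titration_spectra(model, series, 0.0)
        bands = truth.band_params
        wl = ds.wavelengths

        def eps(name, grid):
            from calixtherm.synthgen import _gaussian_bands

            if name == "L":
                return _gaussian_bands(grid, bands["ligand_bands"])
            shift, gain = bands["species_response"]["ML"]
            return _gaussian_bands(
                grid, [(c + shift, w, h * gain) for c, w, h in bands["ligand_bands"]]
            )

        fine = np.linspace(wl[0], wl[-1], 4001)
        diff = eps("L", fine) - eps("ML", fine)
        crossings = fine[:-1][np.diff(np.sign(diff)) != 0]
        assert len(crossings) >= 1
        for lam in crossings:
            values = [np.interp(lam, wl, ds.responses[i]) for i in range(ds.series.n_points)]
            spread = np.ptp(values) / np.mean(values)
            assert spread < 5e-3  # grid-interpolation limited

    def test_linear_then_plateau_for_very_stable_complex(self):
        # complex-band response: linear to the equivalence point, flat after
        ratios = np.linspace(0.05, 2.0, 40)
        series = constant_ligand_series(ratios=ratios)
        ds, _ = synthgen.gen_titration_spectra(make_1to1_model(10.5), series, 0.0)
        band = np.argmin(np.abs(ds.wavelengths - 367.0))  # complex band
        resp = ds.responses[:, band]
        pre, post = ratios <= 0.95, ratios >= 1.05
        slope_pre, icept = np.polyfit(ratios[pre], resp[pre], 1)
        r2 = 1 - np.sum((resp[pre] - (slope_pre * ratios[pre] + icept)) ** 2) / np.sum(
            (resp[pre] - resp[pre].mean()) ** 2
        )
        slope_post = np.polyfit(ratios[post], resp[post], 1)[0]
        assert r2 > 0.999
        assert abs(slope_post) < 0.01 * abs(slope_pre)
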