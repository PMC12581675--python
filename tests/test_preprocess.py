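import numpy as np
import pytest

from ramanfp import (
    AsLSParams,
    PreprocessConfig,
    Spectrum,
    SpectrumSet,
    asls_baseline,
    average_to_fingerprint,
    despike,
    normalize,
)
from ramanfp.preprocess import _resample

from oracles import dense_asls, dense_whittaker, random_band_spectrum


def smooth_spectrum(n=200, noise_sd=0.0, seed=1):
    """Band on a gentle slope; optional measurement noise so the
    first-difference scale is realistic rather than degenerate."""
    x = np.arange(600.0, 600.0 + n)
    y = 1.0 + 1e-3 * (x - 600) + np.exp(-0.5 * ((x - 700) / 15.0) ** 2)
    if noise_sd:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(n)
    return Spectrum(x, y)


class TestDespike:
    def test_smooth_spectrum_unchanged(self):
        s = smooth_spectrum(noise_sd=0.01)
        out = despike(s, z_threshold=8.0)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_single_spike_replaced_by_neighbour_mean(self):
        s = smooth_spectrum(noise_sd=0.01)
        y = s.intensities.copy()
        i = 80
        y[i] = 100.0 * y[i]
        out = despike(Spectrum(s.wavenumbers, y), z_threshold=8.0)
        expected = 0.5 * (y[i - 1] + y[i + 1])  # uniform grid: interp = mean
        assert out.intensities[i] == pytest.approx(expected, rel=1e-12)
        untouched = np.delete(np.arange(len(y)), i)
        np.testing.assert_array_equal(out.intensities[untouched], y[untouched])

    def test_adjacent_spikes_bridged(self):
        s = smooth_spectrum(noise_sd=0.01)
        y = s.intensities.copy()
        y[90] += 50.0
        y[91] += 30.0  # unequal heights: all three diffs around the run are extreme
        out = despike(Spectrum(s.wavenumbers, y), z_threshold=8.0)
        # both flagged, interpolation spans the run between points 89 and 92
        for i, frac in ((90, 1 / 3), (91, 2 / 3)):
            expected = y[89] + frac * (y[92] - y[89])
            assert out.intensities[i] == pytest.approx(expected, rel=1e-9)

    def test_requires_minimum_length(self):
        with pytest.raises(ValueError, match="8 points"):
            despike(Spectrum(np.arange(5.0), np.ones(5)))


class TestAsLS:
    def test_constant_spectrum_returns_itself(self):
        s = Spectrum(np.arange(600.0, 700.0), np.full(100, 3.7))
        z = asls_baseline(s, AsLSParams())
        np.testing.assert_allclose(z, 3.7, atol=1e-6)

    @pytest.mark.parametrize("lam,p", [(1e4, 0.01), (1e5, 0.05)])
    def test_banded_solver_matches_dense_oracle(self, rng, lam, p):
        for _ in range(5):
            x, y = random_band_spectrum(rng, n=200)
            z = asls_baseline(Spectrum(x + 600, y), AsLSParams(lam=lam, p=p))
            z_oracle = dense_asls(y, lam, p)
            rel = np.max(np.abs(z - z_oracle)) / np.max(np.abs(z_oracle))
            assert rel < 1e-8

    def test_symmetric_limit_is_whittaker_smoother(self, rng):
        """p = 0.5 never updates the weights, so AsLS must equal a plain
        weighted Whittaker smooth at w = 0.5."""
        x, y = random_band_spectrum(rng, n=150)
        z = asls_baseline(Spectrum(x + 600, y), AsLSParams(lam=1e4, p=0.5))
        z_oracle = dense_whittaker(y, 1e4, weights=np.full(len(y), 0.5))
        assert np.max(np.abs(z - z_oracle)) / np.max(np.abs(z_oracle)) < 1e-8

    def test_linear_baseline_recovered_away_from_band(self):
        """Line + one strong Gaussian band: the line penalizes to zero, so
        the estimate tracks it within 2% outside 3 FWHM of the band."""
        x = np.arange(600.0, 1801.0)
        line = 2.0 + 1e-3 * (x - 600)
        band = 5.0 * np.exp(-0.5 * ((x - 1200) / 10.0) ** 2)
        z = asls_baseline(Spectrum(x, line + band), AsLSParams(lam=1e5, p=0.01))
        mask = np.abs(x - 1200) >= 3 * 2.3548 * 10.0
        assert np.max(np.abs(z - line)[mask] / line[mask]) < 0.02

    def test_roughness_monotone_in_lam(self, rng):
        x, y = random_band_spectrum(rng, n=300)
        s = Spectrum(x + 600, y)
        roughness = []
        for lam in (1e2, 1e3, 1e4, 1e5, 1e6):
            z = asls_baseline(s, AsLSParams(lam=lam))
            roughness.append(float(np.sum(np.diff(z, 2) ** 2)))
        assert all(a >= b - 1e-15 for a, b in zip(roughness, roughness[1:]))


class TestNormalize:
    def test_l2_unit_norm(self, rng):
        s = Spectrum(np.arange(600.0, 700.0), rng.random(100) + 0.1)
        out = normalize(s, "l2")
        assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_rejected(self):
        s = Spectrum(np.arange(600.0, 700.0), np.zeros(100))
        with pytest.raises(ValueError, match="all-zero"):
            normalize(s, "l2")

    def test_area_mode_matches_hand_trapezoid(self):
        # unit-height rectangle over 10 grid steps embedded in zeros:
        # trapezoid picks up half-height triangles at both edges
        x = np.arange(600.0, 650.0)
        y = np.zeros(50)
        y[10:21] = 1.0  # 11 points spanning 10 cm^-1
        hand = 10.0 + 2 * 0.5  # interior rectangle + two edge triangles
        out = normalize(Spectrum(x, y), "area")
        np.testing.assert_allclose(out.intensities, y / hand, rtol=1e-12)

    def test_none_is_identity(self):
        s = smooth_spectrum()
        np.testing.assert_array_equal(normalize(s, "none").intensities, s.intensities)


class TestFingerprintAveraging:
    def config(self):
        return PreprocessConfig(grid_start=600, grid_stop=799, grid_step=1.0)

    def band_replicate(self, shift=0.0, scale=1.0):
        x = np.arange(595.0, 805.0) + shift
        y = scale * (0.2 + np.exp(-0.5 * ((x - 700) / 12.0) ** 2))
        return Spectrum(x, y)

    def test_identical_replicates_equal_single(self):
        reps30 = SpectrumSet("a", [self.band_replicate() for _ in range(30)])
        rep1 = SpectrumSet("a", [self.band_replicate()])
        f30 = average_to_fingerprint(reps30, self.config())
        f1 = average_to_fingerprint(rep1, self.config())
        np.testing.assert_allclose(f30.intensities, f1.intensities, atol=1e-12)
        assert f30.n_replicates == 30

    def test_l2_fingerprint_on_unit_sphere(self):
        sset = SpectrumSet("a", [self.band_replicate(scale=s) for s in (0.8, 1.0, 1.3)])
        f = average_to_fingerprint(sset, self.config())
        assert np.linalg.norm(f.intensities) == pytest.approx(1.0, abs=1e-12)

    def test_replicate_order_irrelevant(self, rng):
        reps = [self.band_replicate(scale=s) for s in (0.7, 1.0, 1.2, 1.5)]
        f_fwd = average_to_fingerprint(SpectrumSet("a", reps), self.config())
        f_rev = average_to_fingerprint(SpectrumSet("a", reps[::-1]), self.config())
        np.testing.assert_allclose(f_fwd.intensities, f_rev.intensities, atol=1e-12)

    def test_resampling_is_linear_interpolation(self):
        x = np.arange(600.0, 610.0) + 0.5
        s = Spectrum(x, 2.0 * x + 1.0)
        grid = np.arange(601.0, 609.0)
        out = _resample(s, grid, "rep")
        for g in (601.0, 604.0, 608.0):  # linear signal: interpolation exact
            assert out[grid == g][0] == pytest.approx(2.0 * g + 1.0, rel=1e-12)

    def test_replicate_not_covering_grid_is_named(self):
        good = self.band_replicate()
        short = Spectrum(np.arange(650.0, 700.0), np.ones(50), label="short_rep")
        sset = SpectrumSet("a", [good, short])
        with pytest.raises(ValueError, match="short_rep"):
            average_to_fingerprint(sset, self.config())


class TestParamValidation:
    @pytest.mark.parametrize("kw", [{"lam": 0.0}, {"p": 0.0}, {"p": 1.0}, {"max_iter": 0}])
    def test_asls_params(self, kw):
        with pytest.raises(ValueError):
            AsLSParams(**kw)

    def test_grid_step_positive(self):
        with pytest.raises(ValueError):
            PreprocessConfig(grid_step=0.0)
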