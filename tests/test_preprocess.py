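"""Preprocessing chain: apodization, zero-filling, low-rank, B0."""

import numpy as np
import pytest
from sklearn.base import clone

from phosphoshift.preprocess import (
    GaussianApodizer,
    LowRankFilter,
    PreprocSpec,
    SpatialZeroFiller,
    b0_correct,
    gaussian_apodize,
    low_rank_filter,
    spatial_zero_fill,
)
from phosphoshift.simulate import (
    AcquisitionSpec,
    MrsiDataset,
    ResonanceSpec,
    synthesize_fid,
)


def _small_dataset(rng, shape=(4, 4, 4), n_points=256, fill="random"):
    acq = AcquisitionSpec(matrix=shape, n_points=n_points)
    if fill == "random":
        fids = rng.normal(size=shape + (n_points,)) + 1j * rng.normal(size=shape + (n_points,))
    else:
        fids = np.zeros(shape + (n_points,), dtype=complex)
    mask = np.ones(shape, dtype=bool)
    return MrsiDataset(fids=fids, acq=acq, b0_map=np.zeros(shape), mask=mask)


class TestGaussianApodize:
    def test_lw_zero_is_identity(self, rng):
        fid = rng.normal(size=64) + 1j * rng.normal(size=64)
        assert np.array_equal(gaussian_apodize(fid, 0.0, 5000.0), fid)

    def test_t0_sample_unchanged_and_contractive(self, rng):
        fid = rng.normal(size=256) + 1j * rng.normal(size=256)
        out = gaussian_apodize(fid, 25.0, 5000.0)
        assert out[0] == fid[0]
        assert np.all(np.abs(out) <= np.abs(fid) + 1e-15)

    def test_negative_lw_rejected(self):
        with pytest.raises(ValueError):
            gaussian_apodize(np.zeros(16, dtype=complex), -1.0, 5000.0)

    def test_linewidths_add_in_quadrature(self):
        # FFT linewidth oracle: Gaussian FWHM 10 Hz apodized by 15 Hz must
        # show spectral FWHM sqrt(10^2 + 15^2) Hz within 2 %
        bw, n = 5000.0, 4096
        t = np.arange(n) / bw
        fid = np.exp(-((np.pi * 10.0 * t) ** 2) / (4 * np.log(2))).astype(complex)
        out = gaussian_apodize(fid, 15.0, bw)

        def fwhm(x):
            spec = np.fft.fft(x, n=16 * n).real
            spec = np.fft.fftshift(spec)
            freqs = np.fft.fftshift(np.fft.fftfreq(16 * n, d=1 / bw))
            half = spec.max() / 2
            above = freqs[spec >= half]
            return above.max() - above.min()

        assert fwhm(out) == pytest.approx(np.hypot(10.0, 15.0), rel=0.02)


class TestSpatialZeroFill:
    def test_factor_one_identity(self, rng):
        ds = _small_dataset(rng)
        assert spatial_zero_fill(ds, 1) is ds

    def test_factor_two_doubles_grid(self, rng):
        ds = _small_dataset(rng)
        out = spatial_zero_fill(ds, 2)
        assert out.fids.shape == (8, 8, 8, 256)
        assert out.acq.matrix == (8, 8, 8)
        assert out.mask.shape == (8, 8, 8)

    def test_matches_closed_form_fourier_interpolation(self, rng):
        # oracle: evaluate the centred DFT series at half-integer voxel
        # coordinates; zero-filling must agree to 1e-10
        n = 4
        ds = _small_dataset(rng, shape=(n, n, n), n_points=256)
        out = spatial_zero_fill(ds, 2)

        k = np.fft.fftshift(np.fft.fftn(ds.fids, axes=(0, 1, 2)), axes=(0, 1, 2))
        q = np.arange(n) - n // 2  # centred frequency indices
        m = np.arange(2 * n)
        # per-axis DFT basis at new coordinates j = m/2 in original units
        basis = np.exp(2j * np.pi * np.outer(m, q) / (2 * n)) / n
        oracle = np.einsum("ai,bj,ck,ijkt->abct", basis, basis, basis, k)
        assert np.max(np.abs(out.fids - oracle)) < 1e-10

    def test_invalid_factor(self, rng):
        with pytest.raises(ValueError):
            spatial_zero_fill(_small_dataset(rng), 3)


class TestLowRank:
    def test_exact_low_rank_input_preserved(self, rng):
        # data spanned by 3 distinct voxel spectra pass a rank-3 filter
        ds = _small_dataset(rng, fill="zeros")
        basis = rng.normal(size=(3, 256)) + 1j * rng.normal(size=(3, 256))
        coeff = rng.normal(size=(64, 3))
        ds.fids[:] = (coeff @ basis).reshape(4, 4, 4, 256)
        out = low_rank_filter(ds, 3)
        rel = np.linalg.norm(out.fids - ds.fids) / np.linalg.norm(ds.fids)
        assert rel < 1e-8

    def test_full_rank_is_identity(self, rng):
        ds = _small_dataset(rng)
        out = low_rank_filter(ds, min(64, 256))
        assert np.allclose(out.fids, ds.fids, atol=1e-10)

    def test_residual_equals_trailing_singular_energy(self, rng):
        ds = _small_dataset(rng)
        rank = 8
        out = low_rank_filter(ds, rank)
        resid = np.linalg.norm(ds.fids[ds.mask] - out.fids[ds.mask]) ** 2
        s = np.linalg.svd(ds.fids[ds.mask], compute_uv=False)
        trailing = np.sum(s[rank:] ** 2)
        assert resid == pytest.approx(trailing, rel=0.2)

    def test_rank_bounds(self, rng):
        ds = _small_dataset(rng)
        with pytest.raises(ValueError):
            low_rank_filter(ds, 0)
        with pytest.raises(ValueError):
            low_rank_filter(ds, 10_000)


class TestB0Correct:
    def test_zero_offset_identity(self):
        fid = np.ones(64, dtype=complex)
        assert np.allclose(b0_correct(fid, 0.0, bandwidth=5000.0), fid)

    def test_group_inverse(self, rng):
        fid = rng.normal(size=256) + 1j * rng.normal(size=256)
        out = b0_correct(b0_correct(fid, 7.3, bandwidth=5000.0), -7.3, bandwidth=5000.0)
        assert np.max(np.abs(out - fid)) < 1e-12

    def test_correction_recentres_fitted_shift(self):
        # +3 Hz offset synthesized, corrected with +3 Hz → PCr fits at 0 ppm
        from phosphoshift.amares import PriorModel, PriorResonance, fit_voxel

        acq = AcquisitionSpec()
        fid = synthesize_fid([ResonanceSpec("PCr", 0.0, 1.0, 20.0)], acq, b0_offset=3.0)
        corrected = b0_correct(fid, 3.0, bandwidth=acq.bandwidth)
        prior = PriorModel(resonances=(PriorResonance("PCr", 0.0, 1.0, 20.0),))
        fit = fit_voxel(corrected, prior, acq)
        assert abs(fit.get("PCr")) < 1e-4


class TestLinearity:
    def test_apodize_and_zero_fill_are_linear(self, rng):
        ds1 = _small_dataset(rng)
        ds2 = _small_dataset(rng)
        for op in (
            lambda d: gaussian_apodize(d, 15.0, 5000.0),
            lambda d: spatial_zero_fill(
                MrsiDataset(d, ds1.acq, ds1.b0_map, ds1.mask), 2
            ).fids,
        ):
            lhs = op(ds1.fids + ds2.fids)
            rhs = op(ds1.fids) + op(ds2.fids)
            assert np.linalg.norm(lhs - rhs) <= 1e-10 * np.linalg.norm(rhs)


class TestEstimators:
    def test_transformers_are_sklearn_compatible(self, rng):
        X = rng.normal(size=(10, 128)) + 1j * rng.normal(size=(10, 128))
        for est in (GaussianApodizer(), LowRankFilter(rank=2), SpatialZeroFiller()):
            cloned = clone(est)
            assert cloned.get_params() == est.get_params()
        apod = GaussianApodizer(lw_hz=15.0, bandwidth_hz=5000.0).fit(X)
        assert apod.transform(X).shape == X.shape
        lr = LowRankFilter(rank=2).fit(X)
        out = lr.transform(X)
        assert np.linalg.matrix_rank(out, tol=1e-8) <= 2


class TestPreprocSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PreprocSpec(gaussian_lw=-1)
        with pytest.raises(ValueError):
            PreprocSpec(spatial_zf_factor=3)
        with pytest.raises(ValueError):
            PreprocSpec(lowrank_rank=0)
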