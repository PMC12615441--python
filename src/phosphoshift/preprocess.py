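"""Post-processing chain applied before spectral quantification.

The fixed order is: low-rank (Casorati) filtering → spatial zero-filling →
time-domain Gaussian apodization.  All steps are linear operators.

Estimator classes follow scikit-learn conventions (``get_params`` /
``set_params`` / ``transform``) so they compose with sklearn pipelines;
the module-level functions are thin wrappers used by the MRSI pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import GroundTruth, MrsiDataset

__all__ = [
    "PreprocSpec",
    "gaussian_window",
    "gaussian_apodize",
    "spatial_zero_fill",
    "low_rank_filter",
    "b0_correct",
    "upsample_truth",
    "GaussianApodizer",
    "LowRankFilter",
    "SpatialZeroFiller",
]

_4LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class PreprocSpec:
    """Preprocessing parameters.

    ``gaussian_lw`` is the added Gaussian linewidth (FWHM, Hz);
    ``spatial_zf_factor`` 2 means "one-fold" zero-filling (doubled grid);
    ``lowrank_rank`` of ``None`` disables the low-rank filter.
    """

    gaussian_lw: float = 15.0
    spatial_zf_factor: int = 2
    lowrank_rank: int | None = 8

    def __post_init__(self) -> None:
        if self.gaussian_lw < 0:
            raise ValueError("gaussian_lw must be ≥ 0")
        if self.spatial_zf_factor not in (1, 2):
            raise ValueError("spatial_zf_factor must be 1 or 2")
        if self.lowrank_rank is not None and self.lowrank_rank < 1:
            raise ValueError("lowrank_rank must be ≥ 1 when set")


def gaussian_window(lw: float, n_points: int, bandwidth: float) -> np.ndarray:
    """w(t) = exp(−(π·lw·t)²/(4 ln 2)): multiplying an FID by this adds a
    Gaussian line broadening of FWHM ``lw`` Hz; w(0) = 1."""
    t = np.arange(n_points) / bandwidth
    return np.exp(-((np.pi * lw * t) ** 2) / _4LN2)


def gaussian_apodize(fid: np.ndarray, lw: float, bandwidth: float) -> np.ndarray:
    """Apply the Gaussian time-domain filter along the last axis."""
    if lw < 0:
        raise ValueError("lw must be ≥ 0")
    if lw == 0:
        return fid.copy()
    return fid * gaussian_window(lw, fid.shape[-1], bandwidth)


def _zero_fill_array(fids: np.ndarray, factor: int) -> np.ndarray:
    """Fourier-interpolate the spatial grid of an (x, y, z, t) array.

    k-space is centred with fftshift; for even grid sizes the original
    coefficients occupy the central block, which pads by n/2 on each side
    (the Nyquist row stays on the negative-frequency side).  The output is
    scaled by factor³ so voxel signal amplitudes stay comparable.
    """
    spatial = fids.shape[:3]
    k = np.fft.fftshift(np.fft.fftn(fids, axes=(0, 1, 2)), axes=(0, 1, 2))
    new_shape = tuple(factor * n for n in spatial)
    pad = [((fn - n) // 2, fn - n - (fn - n) // 2) for n, fn in zip(spatial, new_shape)]
    k = np.pad(k, pad + [(0, 0)])
    out = np.fft.ifftn(np.fft.ifftshift(k, axes=(0, 1, 2)), axes=(0, 1, 2))
    return out * factor ** 3


def _upsample_nearest(vol: np.ndarray, factor: int) -> np.ndarray:
    for ax in range(3):
        vol = np.repeat(vol, factor, axis=ax)
    return vol


def spatial_zero_fill(dataset: MrsiDataset, factor: int) -> MrsiDataset:
    """Zero-fill k-space to ``factor``× the spatial matrix.

    FIDs are Fourier-interpolated; the mask and B0 map are upsampled by
    nearest-neighbour replication (labels and maps cannot be Fourier
    interpolated).  ``factor = 1`` is the identity.
    """
    if factor not in (1, 2):
        raise ValueError("zero-fill factor must be 1 or 2")
    if factor == 1:
        return dataset
    new_fids = _zero_fill_array(dataset.fids, factor)
    new_mask = _upsample_nearest(dataset.mask, factor)
    new_b0 = _upsample_nearest(dataset.b0_map, factor)
    new_b0[~new_mask] = 0.0
    acq = replace(dataset.acq, matrix=tuple(factor * m for m in dataset.acq.matrix))
    return MrsiDataset(fids=new_fids, acq=acq, b0_map=new_b0, mask=new_mask)


def upsample_truth(truth: GroundTruth, factor: int) -> GroundTruth:
    """Replicate ground-truth volumes onto the zero-filled grid."""
    if factor == 1:
        return truth
    return GroundTruth(
        ph=_upsample_nearest(truth.ph, factor),
        mg=_upsample_nearest(truth.mg, factor),
        ion=_upsample_nearest(truth.ion, factor),
        labels=_upsample_nearest(truth.labels, factor),
        patient_id=truth.patient_id,
        grade=truth.grade,
        idh=truth.idh,
    )


def _casorati_truncate(mat: np.ndarray, rank: int) -> np.ndarray:
    u, s, vh = np.linalg.svd(mat, full_matrices=False)
    return (u[:, :rank] * s[:rank]) @ vh[:rank]


def low_rank_filter(dataset: MrsiDataset, rank: int) -> MrsiDataset:
    """Truncated-SVD denoising of the Casorati matrix (mask voxels × time).

    Keeps the best rank-``rank`` Frobenius approximation of the in-mask
    Casorati matrix; voxels outside the mask pass through unchanged.
    """
    n_vox = int(dataset.mask.sum())
    n_t = dataset.fids.shape[-1]
    if not (1 <= rank <= min(n_vox, n_t)):
        raise ValueError(f"rank must be in [1, {min(n_vox, n_t)}]")
    cas = dataset.fids[dataset.mask]
    out = dataset.fids.copy()
    out[dataset.mask] = _casorati_truncate(cas, rank)
    return MrsiDataset(fids=out, acq=dataset.acq, b0_map=dataset.b0_map, mask=dataset.mask)


def b0_correct(fid_or_dataset, b0, bandwidth: float | None = None):
    """Demodulate the B0 offset: multiply each FID by exp(−i·2π·b0·t).

    Accepts a single FID (with ``b0`` a scalar and ``bandwidth`` given) or
    an :class:`MrsiDataset` (with ``b0`` a per-voxel Hz map, defaulting to
    the dataset's own).  Correcting with ``b`` then ``−b`` is the identity.
    """
    if isinstance(fid_or_dataset, MrsiDataset):
        ds = fid_or_dataset
        b0_map = ds.b0_map if b0 is None else b0
        t = ds.acq.times
        phase = np.exp(-2j * np.pi * b0_map[..., None] * t)
        new_b0 = ds.b0_map - b0_map
        new_b0[~ds.mask] = 0.0
        return MrsiDataset(fids=ds.fids * phase, acq=ds.acq, b0_map=new_b0, mask=ds.mask)
    if bandwidth is None:
        raise ValueError("bandwidth required when correcting a bare FID")
    t = np.arange(fid_or_dataset.shape[-1]) / bandwidth
    return fid_or_dataset * np.exp(-2j * np.pi * b0 * t)


def apply_chain(dataset: MrsiDataset, spec: PreprocSpec) -> MrsiDataset:
    """Run the fixed-order chain: low-rank → zero-fill → apodize."""
    ds = dataset
    if spec.lowrank_rank is not None:
        ds = low_rank_filter(ds, spec.lowrank_rank)
    ds = spatial_zero_fill(ds, spec.spatial_zf_factor)
    if spec.gaussian_lw > 0:
        ds = MrsiDataset(
            fids=gaussian_apodize(ds.fids, spec.gaussian_lw, ds.acq.bandwidth),
            acq=ds.acq, b0_map=ds.b0_map, mask=ds.mask,
        )
    return ds


# -- scikit-learn estimator surface ---------------------------------------

class GaussianApodizer(TransformerMixin, BaseEstimator):
    """Transformer applying the Gaussian time-domain filter to FID rows.

    X is a complex array whose last axis is time.
    """

    def __init__(self, lw_hz: float = 15.0, bandwidth_hz: float = 5000.0):
        self.lw_hz = lw_hz
        self.bandwidth_hz = bandwidth_hz

    def fit(self, X, y=None):
        if self.lw_hz < 0:
            raise ValueError("lw_hz must be ≥ 0")
        return self

    def transform(self, X):
        return gaussian_apodize(np.asarray(X), self.lw_hz, self.bandwidth_hz)


class LowRankFilter(TransformerMixin, BaseEstimator):
    """Transformer truncating a Casorati matrix (rows = voxels) to a fixed rank."""

    def __init__(self, rank: int = 8):
        self.rank = rank

    def fit(self, X, y=None):
        X = np.asarray(X)
        if not (1 <= self.rank <= min(X.shape)):
            raise ValueError(f"rank must be in [1, {min(X.shape)}]")
        return self

    def transform(self, X):
        X = np.asarray(X)
        rank = min(self.rank, min(X.shape))
        return _casorati_truncate(X, rank)


class SpatialZeroFiller(TransformerMixin, BaseEstimator):
    """Transformer Fourier-interpolating the spatial grid of an (x, y, z, t) array."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def fit(self, X, y=None):
        if self.factor not in (1, 2):
            raise ValueError("factor must be 1 or 2")
        return self

    def transform(self, X):
        X = np.asarray(X)
        if self.factor == 1:
            return X
        return _zero_fill_array(X, self.factor)
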