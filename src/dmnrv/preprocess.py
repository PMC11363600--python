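"""BOLD preprocessing: volume discard, smoothing, detrend, bandpass, nuisance regression.

The chain mirrors a standard resting-state pipeline operating on already
spatially-aligned data: discard initial volumes, smooth with an isotropic
Gaussian, remove the per-voxel linear trend, apply an ideal rectangular
bandpass in the DFT domain (0.01-0.08 Hz by default), then regress out
motion regressors and the leading principal components of the white-matter
and CSF compartment time courses (CompCor-style).

The ideal DFT filter (rather than an IIR design such as Butterworth) is
used deliberately: it is the dialect of the classic resting-state toolkits
and is exactly idempotent, which makes the filter contract testable to
machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BoldSeries, NuisanceSet, RoiAtlas

logger = logging.getLogger(__name__)

#: FWHM -> sigma conversion constant, 2 * sqrt(2 * ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default passband in Hz.
DEFAULT_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class FilterBand:
    """A [low_hz, high_hz] passband; must sit strictly inside (0, Nyquist)."""

    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 <= self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz invalid for TR="
                f"{tr_seconds}s (Nyquist {nyquist:.4f} Hz)")


@dataclass
class PreprocParams:
    """Tunable preprocessing parameters with their conventional defaults."""

    discard_k: int = 3
    fwhm_mm: float = 4.0
    band: FilterBand = field(default_factory=FilterBand)
    n_wm_pcs: int = 5
    n_csf_pcs: int = 5
    regress_nuisance: bool = True
    smooth: bool = True


def discard_initial_volumes(series: BoldSeries, k: int = 3) -> BoldSeries:
    """Drop the first ``k`` volumes (T1-equilibration scrub)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if series.n_timepoints <= k:
        raise ValueError(
            f"cannot discard {k} volumes from a series of {series.n_timepoints}")
    if k == 0:
        return series.with_data(series.data.copy())
    return series.with_data(series.data[..., k:])


def smoothing_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> tuple[float, float, float]:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return tuple(fwhm_mm / FWHM_TO_SIGMA / v for v in voxel_size_mm)


def gaussian_smooth(series: BoldSeries, fwhm_mm: float = 4.0) -> BoldSeries:
    """Convolve each volume with an isotropic Gaussian (zero-padded edges)."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma = smoothing_sigma_voxels(fwhm_mm, series.voxel_size_mm)
    out = ndimage.gaussian_filter(series.data, sigma=sigma + (0.0,),
                                  mode="constant", cval=0.0)
    return series.with_data(out)


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel least-squares line a + b*t (mean and drift).

    Closed-form projection: with centred time ``tc``, the slope is
    ``<x, tc> / <tc, tc>`` and the residual is ``x - mean - slope * tc``,
    identical to solving the normal equations for [1, t].
    """
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    data = series.data
    t = np.arange(data.shape[-1], dtype=np.float64)
    tc = t - t.mean()
    mean = data.mean(axis=-1, keepdims=True)
    slope = (data @ tc) / (tc @ tc)
    return series.with_data(data - mean - slope[..., None] * tc)


def bandpass_array(data: np.ndarray, tr_seconds: float, band: FilterBand) -> np.ndarray:
    """Ideal rectangular DFT bandpass along the last axis.

    Frequency bins with ``low_hz <= f <= high_hz`` are retained; everything
    else — including DC — is zeroed, and the inverse transform is returned.
    The operation is exactly idempotent.
    """
    band.validate(tr_seconds)
    t = data.shape[-1]
    spec = np.fft.rfft(data, axis=-1)
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def bandpass(series: BoldSeries, band: FilterBand | None = None) -> BoldSeries:
    band = band or FilterBand()
    return series.with_data(bandpass_array(series.data, series.tr_seconds, band))


def extract_tissue_pcs(series: BoldSeries, atlas: RoiAtlas, compartment: str,
                       n_pcs: int, return_variance: bool = False):
    """Top principal-component time courses of a tissue compartment.

    The compartment's voxel x time matrix is centred per voxel over time and
    decomposed by SVD; the leading ``n_pcs`` right singular vectors (unit
    norm, ordered by decreasing explained variance) are returned as a
    (t, n_pcs) array.  Signs are fixed so each component's largest-magnitude
    sample is positive.
    """
    if compartment not in ("wm", "csf"):
        raise ValueError(f"compartment must be 'wm' or 'csf', got {compartment!r}")
    mask = atlas.region_mask(compartment)
    if not mask.any():
        raise ValueError(f"compartment {compartment!r} is empty in the atlas")
    mat = series.data[mask]  # (voxels, t)
    mat = mat - mat.mean(axis=1, keepdims=True)
    if n_pcs < 0:
        raise ValueError("n_pcs must be non-negative")
    t = mat.shape[1]
    if n_pcs == 0:
        pcs = np.empty((t, 0))
        return (pcs, np.empty(0)) if return_variance else pcs
    svals = np.linalg.svd(mat, compute_uv=False)
    rank = int(np.sum(svals > svals[0] * max(mat.shape) * np.finfo(float).eps)) if svals.size else 0
    if n_pcs > min(mat.shape) or n_pcs > rank:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the rank ({rank}) of the {compartment} matrix")
    _, s, vt = np.linalg.svd(mat, full_matrices=False)
    pcs = vt[:n_pcs].T  # (t, n_pcs), unit columns
    flip = np.sign(pcs[np.argmax(np.abs(pcs), axis=0), np.arange(n_pcs)])
    flip[flip == 0] = 1.0
    pcs = pcs * flip
    explained = s[:n_pcs] ** 2 / np.sum(s ** 2)
    return (pcs, explained) if return_variance else pcs


def _name_collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan: columns that add nothing to the rank of their predecessors."""
    bad, cols = [], []
    rank = 0
    for j in range(design.shape[1]):
        cols.append(design[:, j])
        new_rank = np.linalg.matrix_rank(np.column_stack(cols))
        if new_rank == rank:
            bad.append(names[j])
            cols.pop()
        rank = new_rank
    return bad


def nuisance_regress(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Per-voxel least-squares residual on [intercept, motion, wm PCs, csf PCs]."""
    t = series.n_timepoints
    if nuisance.n_timepoints != t:
        raise ValueError(
            f"nuisance length {nuisance.n_timepoints} != series length {t}")
    design = np.column_stack([np.ones(t), nuisance.columns()])
    names = ["intercept"] + nuisance.column_names()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _name_collinear_columns(design, names)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    flat = series.data.reshape(-1, t).T  # (t, voxels)
    q, _ = np.linalg.qr(design)  # orthonormal basis of the design span
    resid = flat - q @ (q.T @ flat)
    return series.with_data(resid.T.reshape(series.data.shape))


def preprocess_subject(series: BoldSeries, atlas: RoiAtlas,
                       motion: np.ndarray | None = None,
                       params: PreprocParams | None = None) -> BoldSeries:
    """Run the full chain: discard -> smooth -> detrend -> bandpass -> nuisance.

    ``motion`` is the (t, 6) motion regressor matrix for the *original*
    series; its first ``discard_k`` rows are dropped alongside the volumes.
    WM/CSF principal components are extracted from the filtered series, so
    nuisance removal is self-consistent with the temporal filtering.
    """
    params = params or PreprocParams()
    out = discard_initial_volumes(series, params.discard_k)
    logger.info("discarded %d initial volumes (t=%d)", params.discard_k, out.n_timepoints)
    if params.smooth:
        out = gaussian_smooth(out, params.fwhm_mm)
        logger.info("smoothed with FWHM=%.2f mm", params.fwhm_mm)
    out = linear_detrend(out)
    out = bandpass(out, params.band)
    logger.info("detrended and bandpassed to [%.3f, %.3f] Hz",
                params.band.low_hz, params.band.high_hz)
    if params.regress_nuisance:
        if motion is None:
            raise ValueError("nuisance regression requested but no motion regressors given")
        motion = np.asarray(motion, dtype=np.float64)
        if motion.shape[0] == series.n_timepoints:
            motion = motion[params.discard_k:]
        if motion.shape[0] != out.n_timepoints:
            raise ValueError("motion regressor length does not match the series")
        wm = extract_tissue_pcs(out, atlas, "wm", params.n_wm_pcs)
        csf = extract_tissue_pcs(out, atlas, "csf", params.n_csf_pcs)
        nuisance = NuisanceSet(motion=motion, wm_pcs=wm, csf_pcs=csf)
        out = nuisance_regress(out, nuisance)
        logger.info("regressed 6 motion + %d WM + %d CSF components",
                    wm.shape[1], csf.shape[1])
    return out
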