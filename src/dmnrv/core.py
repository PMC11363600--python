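"""Core data containers and NIfTI I/O.

The pipeline operates on three in-memory objects: a subject's 4D BOLD
series, a 3D integer-labelled ROI atlas, and the per-subject nuisance
regressor set.  Arrays are plain float64 numpy arrays; NIfTI-1 is the
on-disk format (via nibabel) with the voxel size carried in the affine
and the repetition time in the time-axis zoom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Names of the default-mode-network subregions modelled by the atlas.
DMN_REGIONS = ("anterior", "posterior", "ventral")

#: Tissue compartments used for CompCor-style nuisance extraction.
COMPARTMENTS = ("wm", "csf")

REGION_NAMES = DMN_REGIONS + COMPARTMENTS


@dataclass
class BoldSeries:
    """A subject's 4D BOLD array (x, y, z, t) plus scan metadata.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal in arbitrary units; must be finite.
    tr_seconds : float
        Repetition time in seconds.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths along x, y, z in millimetres.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t); got ndim={self.data.ndim}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive floats")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Return a copy carrying ``data`` with unchanged metadata."""
        return BoldSeries(data=data, tr_seconds=self.tr_seconds,
                          voxel_size_mm=self.voxel_size_mm)


@dataclass
class RoiAtlas:
    """3D integer label volume with a name -> label code map.

    ``code_map`` must name the three DMN subregions (anterior, posterior,
    ventral) and the wm / csf compartments; 0 is background.
    """

    labels: np.ndarray
    code_map: dict[str, int] = field(default_factory=dict)
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels).tolist())
        for name, code in self.code_map.items():
            if code <= 0:
                raise ValueError(f"label code for {name!r} must be positive")
            if code not in present:
                raise ValueError(f"label {code} for region {name!r} absent from the volume")

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of a named region; unions accepted as tuples of names."""
        if region not in self.code_map:
            raise KeyError(f"unknown region {region!r}; known: {sorted(self.code_map)}")
        return self.labels == self.code_map[region]

    def union_mask(self, regions: tuple[str, ...]) -> np.ndarray:
        mask = np.zeros(self.labels.shape, dtype=bool)
        for region in regions:
            mask |= self.region_mask(region)
        return mask

    def region_size(self, region: str) -> int:
        return int(self.region_mask(region).sum())


@dataclass
class NuisanceSet:
    """Per-subject nuisance regressors, all length-matched to the series.

    ``motion`` holds six motion-like time series (t, 6); ``wm_pcs`` and
    ``csf_pcs`` hold CompCor-style principal-component time courses
    (t, k each, possibly k = 0).
    """

    motion: np.ndarray
    wm_pcs: np.ndarray
    csf_pcs: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=np.float64))
        self.wm_pcs = np.asarray(self.wm_pcs, dtype=np.float64).reshape(self.motion.shape[0], -1)
        self.csf_pcs = np.asarray(self.csf_pcs, dtype=np.float64).reshape(self.motion.shape[0], -1)
        if self.motion.shape[1] != 6:
            raise ValueError(f"expected 6 motion regressors, got {self.motion.shape[1]}")
        for name, arr in (("motion", self.motion), ("wm_pcs", self.wm_pcs),
                          ("csf_pcs", self.csf_pcs)):
            if arr.size and np.any(np.var(arr, axis=0) == 0):
                raise ValueError(f"{name} contains a zero-variance column")

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]

    def columns(self) -> np.ndarray:
        """All regressors stacked as a (t, 6 + k_wm + k_csf) matrix."""
        return np.hstack([self.motion, self.wm_pcs, self.csf_pcs])

    def column_names(self) -> list[str]:
        names = [f"motion_{i}" for i in range(6)]
        names += [f"wm_pc_{i}" for i in range(self.wm_pcs.shape[1])]
        names += [f"csf_pc_{i}" for i in range(self.csf_pcs.shape[1])]
        return names

    def truncate(self, k: int) -> "NuisanceSet":
        """Drop the first ``k`` time points (mirrors initial-volume discard)."""
        return NuisanceSet(self.motion[k:], self.wm_pcs[k:], self.csf_pcs[k:])


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_series(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(series.data, _affine(series.voxel_size_mm))
    img.header.set_zooms(series.voxel_size_mm + (series.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_series(path) -> BoldSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    return BoldSeries(np.asarray(img.dataobj, dtype=np.float64), tr_seconds=tr,
                      voxel_size_mm=tuple(float(z) for z in zooms[:3]))


def save_atlas(atlas: RoiAtlas, path) -> None:
    voxel_size_mm = (atlas.voxel_size_mm,) * 3
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(voxel_size_mm))
    # region name -> code map travels in the NIfTI description field
    desc = ";".join(f"{k}={v}" for k, v in sorted(atlas.code_map.items()))
    img.header["descrip"] = desc.encode()[:79]
    nib.save(img, str(path))


def load_atlas(path) -> RoiAtlas:
    img = nib.load(str(path))
    desc = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
    code_map = {}
    for item in filter(None, desc.split(";")):
        name, _, code = item.partition("=")
        code_map[name] = int(code)
    vox = float(img.header.get_zooms()[0])
    return RoiAtlas(np.asarray(img.dataobj).astype(np.int32), code_map, voxel_size_mm=vox)
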