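"""ROI-to-voxel (RV) connectivity metrics for the default mode network.

The RV correlation of an ROI is the median Fisher-z of the Pearson
correlations between the ROI's mean time course and every voxel inside
the ROI — a within-region coherence statistic.  Ratios of RV values
between regions ("X to Y" metrics) quantify the relative coherence of
DMN subdivisions; the classic example is the anterior/posterior DMN
RV-ratio.

Ten metrics are produced per subject: six ordered RV ratios and four
"Median" metrics, which are plain RV values of single regions or region
unions:

    anterior to average, anterior to posterior, anterior to ventral,
    average to posterior, average to ventral, posterior to ventral,
    Median posterior, Median anterior-posterior, Median average,
    Median ventral

"average" denotes the composite ROI formed by the union of the anterior,
posterior, and ventral voxel sets, with RV computed against the union's
own mean time course; "Median anterior-posterior" is the RV of the
anterior∪posterior union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DMN_REGIONS, BoldSeries, RoiAtlas

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/- (1 - CLIP_EPS) before the Fisher transform
#: so that degenerate (perfectly coherent) regions stay finite.
CLIP_EPS = 1e-7

#: The six ordered region pairs reported as RV ratios.
RATIO_PAIRS = (
    ("anterior", "average"),
    ("anterior", "posterior"),
    ("anterior", "ventral"),
    ("average", "posterior"),
    ("average", "ventral"),
    ("posterior", "ventral"),
)

#: The four RV ("Median") metrics and the voxel sets they are computed over.
MEDIAN_METRICS = {
    "Median posterior": ("posterior",),
    "Median anterior-posterior": ("anterior", "posterior"),
    "Median average": DMN_REGIONS,
    "Median ventral": ("ventral",),
}

METRIC_NAMES = tuple(f"{a} to {b}" for a, b in RATIO_PAIRS) + tuple(MEDIAN_METRICS)


@dataclass
class ConnectivityMetrics:
    """Per-subject RV values, RV ratios, and excluded-voxel bookkeeping."""

    rv: dict[str, float]
    ratios: dict[str, float]
    excluded_voxel_count: dict[str, int] = field(default_factory=dict)

    def table(self) -> dict[str, float]:
        """The ten named metrics as a flat name -> value map."""
        out = dict(self.ratios)
        for name, regions in MEDIAN_METRICS.items():
            key = "average" if regions == DMN_REGIONS else "+".join(regions)
            out[name] = self.rv[key]
        return {name: out[name] for name in METRIC_NAMES}


def roi_mean_timecourse(series: BoldSeries, atlas: RoiAtlas, region) -> np.ndarray:
    """Unweighted mean over the region's voxels at each time point."""
    mask = atlas.union_mask(region) if isinstance(region, tuple) else atlas.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    return series.data[mask].mean(axis=0)


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r), with clipping near |r| = 1.

    Values with |r| > 1 - 1e-7 are clipped to the bound (and the clip is
    logged) so degenerate correlations stay finite.
    """
    arr = np.asarray(r, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite correlation passed to fisher_z")
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    n_clipped = int(np.sum(np.abs(arr) > 1.0 - CLIP_EPS))
    if n_clipped:
        logger.info("fisher_z: clipped %d correlation(s) at 1 - %g", n_clipped, CLIP_EPS)
    clipped = np.clip(arr, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    z = np.arctanh(clipped)
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


def _rv_from_matrix(mat: np.ndarray) -> tuple[float, int]:
    """Median Fisher-z of voxel-vs-region-mean Pearson correlations.

    ``mat`` is (voxels, t).  Voxels with zero temporal variance are
    excluded from the correlation set (Pearson is undefined there) and
    counted; the region mean is taken over all voxels.
    """
    mean_tc = mat.mean(axis=0)
    # a flat voxel has max == min exactly; variance may carry rounding dust
    usable = np.ptp(mat, axis=1) > 0.0
    excluded = int(np.sum(~usable))
    if np.sum(usable) < 2:
        raise ValueError("fewer than 2 voxels with nonzero temporal variance")
    if np.ptp(mean_tc) == 0.0:
        raise ValueError("region mean time course has zero variance")
    sub = mat[usable]
    sub_c = sub - sub.mean(axis=1, keepdims=True)
    mean_c = mean_tc - mean_tc.mean()
    r = (sub_c @ mean_c) / (np.linalg.norm(sub_c, axis=1) * np.linalg.norm(mean_c))
    z = fisher_z(r)
    return float(np.median(z)), excluded


def rv_correlation(series: BoldSeries, atlas: RoiAtlas, region) -> tuple[float, int]:
    """RV correlation of a region (or tuple of regions, taken as a union).

    Returns ``(rv, excluded)`` where ``excluded`` counts zero-variance
    voxels left out of the median.
    """
    mask = atlas.union_mask(region) if isinstance(region, tuple) else atlas.region_mask(region)
    if int(mask.sum()) < 2:
        raise ValueError(f"region {region!r} has fewer than 2 voxels")
    return _rv_from_matrix(series.data[mask])


def rv_ratio(rv_num: float, rv_den: float) -> float:
    """Ratio of two RV correlations (e.g. the anterior/posterior DMN RV-ratio)."""
    if abs(rv_den) < 1e-12:
        raise ZeroDivisionError(
            "denominator RV is (numerically) zero; the ratio is uninterpretable")
    return rv_num / rv_den


def compute_metric_table(series: BoldSeries, atlas: RoiAtlas,
                         mode: str = "ratio") -> ConnectivityMetrics:
    """All ten DMN connectivity metrics for one subject.

    ``mode='ratio'`` (default) reads "X to Y" as RV(X)/RV(Y).  The
    alternative ``mode='timecourse'`` reads it as the Fisher-z of the
    Pearson correlation between X's and Y's mean time courses, provided
    for sensitivity analysis; the Median metrics are unaffected.
    """
    if mode not in ("ratio", "timecourse"):
        raise ValueError(f"unknown metric mode {mode!r}")
    rv: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for region in DMN_REGIONS:
        rv[region], excluded[region] = rv_correlation(series, atlas, region)
    rv["average"], excluded["average"] = rv_correlation(series, atlas, DMN_REGIONS)
    key_ap = "anterior+posterior"
    rv[key_ap], excluded[key_ap] = rv_correlation(series, atlas, ("anterior", "posterior"))

    ratios: dict[str, float] = {}
    if mode == "ratio":
        for a, b in RATIO_PAIRS:
            ratios[f"{a} to {b}"] = rv_ratio(rv[a], rv[b])
    else:
        tc = {r: roi_mean_timecourse(series, atlas, r) for r in DMN_REGIONS}
        tc["average"] = roi_mean_timecourse(series, atlas, DMN_REGIONS)
        for a, b in RATIO_PAIRS:
            r = np.corrcoef(tc[a], tc[b])[0, 1]
            ratios[f"{a} to {b}"] = fisher_z(r)
    return ConnectivityMetrics(rv=rv, ratios=ratios, excluded_voxel_count=excluded)


def metrics_to_frame(metrics_by_subject: dict[str, ConnectivityMetrics]) -> pd.DataFrame:
    """One row per subject, one column per metric, plus excluded-voxel counts."""
    rows = []
    for subject_id, m in metrics_by_subject.items():
        row = {"subject_id": subject_id, **m.table()}
        row["excluded_voxels_total"] = int(sum(m.excluded_voxel_count.values()))
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
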