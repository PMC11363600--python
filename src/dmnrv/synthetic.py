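"""Synthetic cohort generator: BOLD phantoms plus coupled CSF biomarkers.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access-controlled subject data:

* a tiny labelled atlas with three DMN subregions (anterior, posterior,
  ventral) plus white-matter and CSF compartments;
* per-subject band-limited (0.01-0.08 Hz), region-coherent BOLD signals —
  each voxel in region R is ``sqrt(c)*s_R(t) + sqrt(1-c)*eps(t)`` with a
  subject- and region-specific coherence parameter c — contaminated with
  linear drift, six motion-like regressors, and WM/CSF compartment leakage;
* a phenotype table (two groups, CN n=25 and MCI n=23 by default) whose
  CSF biomarker values are coupled to the planted connectivity at
  configurable target correlations.

Biomarker coupling targets the *planted* coherence parameter, not the
measured RV metric, so measurement noise attenuates observed correlations
exactly as it would in real data; recovery analyses must budget for that
attenuation.  The latent truth (planted c per region, unrounded biomarker
values) is kept alongside the fixtures so estimates can be compared
against it.

Everything is reproducible from the cohort seed; per-subject randomness is
drawn from independent substreams keyed by (seed, subject index), so a
subject's data do not depend on cohort ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import MEDIAN_METRICS, METRIC_NAMES, RATIO_PAIRS
from .core import (COMPARTMENTS, DMN_REGIONS, REGION_NAMES, BoldSeries,
                   NuisanceSet, RoiAtlas, save_atlas, save_series)
from .preprocess import FilterBand, bandpass_array

GROUPS = ("CN", "MCI")
BIOMARKERS = ("gap43", "abeta42", "ttau", "ptau181")

#: Group covariate distributions: age mean/SD in years.
AGE_BY_GROUP = {"CN": (70.62, 5.34), "MCI": (72.77, 5.75)}
#: Female fraction per group (sex coded 0 = female, 1 = male).
FEMALE_FRACTION = {"CN": 15 / 25, "MCI": 11 / 23}
#: Education draw: normal(mean, sd) in years, rounded, clipped to [6, 22].
EDUCATION_BY_GROUP = {"CN": (18.0, 2.0), "MCI": (16.0, 3.0)}
#: MMSE draw: ceiling minus a Poisson deficit, clipped to the given floor.
MMSE_BY_GROUP = {"CN": (30, 0.7, 24), "MCI": (29, 1.3, 19)}

#: Biomarker location/scale in pg/mL used to map standardized draws to levels.
BIOMARKER_MEANS_SDS = {
    "gap43": (5500.0, 2000.0),
    "abeta42": (180.0, 50.0),
    "ttau": (90.0, 35.0),
    "ptau181": (30.0, 12.0),
}

# substream tags so different draw purposes never collide
_STREAM_BOLD = 17
_STREAM_PHENO = 29
_STREAM_TRUTH = 41

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def _box_volume(box: Box) -> int:
    return int(np.prod([hi - lo for lo, hi in box]))


def _boxes_overlap(a: Box, b: Box) -> bool:
    return all(a_lo < b_hi and b_lo < a_hi for (a_lo, a_hi), (b_lo, b_hi) in zip(a, b))


@dataclass(frozen=True)
class AtlasSpec:
    """Geometry of the synthetic atlas: disjoint axis-aligned region boxes."""

    grid_dims: tuple[int, int, int] = (20, 20, 10)
    voxel_size_mm: float = 3.0
    region_boxes: dict[str, Box] = field(default_factory=lambda: {
        "anterior": ((3, 7), (3, 7), (3, 7)),
        "posterior": ((13, 17), (3, 7), (3, 7)),
        "ventral": ((3, 7), (13, 17), (3, 7)),
        "wm": ((13, 17), (13, 17), (3, 7)),
        "csf": ((8, 12), (8, 12), (3, 7)),
    })
    label_codes: dict[str, int] = field(default_factory=lambda: {
        "anterior": 1, "posterior": 2, "ventral": 3, "wm": 4, "csf": 5,
    })

    def validate(self) -> None:
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be three positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        missing = set(REGION_NAMES) - set(self.region_boxes)
        if missing:
            raise ValueError(f"region_boxes missing regions: {sorted(missing)}")
        for name, box in self.region_boxes.items():
            if _box_volume(box) == 0:
                raise ValueError(f"region {name!r} has an empty box")
            for (lo, hi), dim in zip(box, self.grid_dims):
                if not (0 <= lo < hi <= dim):
                    raise ValueError(f"region {name!r} box {box} exceeds grid {self.grid_dims}")
        names = sorted(self.region_boxes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _boxes_overlap(self.region_boxes[a], self.region_boxes[b]):
                    raise ValueError(f"region boxes overlap: {a!r} and {b!r}")
        codes = list(self.label_codes.values())
        if len(set(codes)) != len(codes) or any(c <= 0 for c in codes):
            raise ValueError("label codes must be unique positive integers")
        if set(self.label_codes) != set(self.region_boxes):
            raise ValueError("label_codes and region_boxes must name the same regions")


def compact_atlas_spec() -> AtlasSpec:
    """A 12x12x10 grid with 3-voxel cubic ROIs, for fast simulation studies."""
    return AtlasSpec(
        grid_dims=(12, 12, 10),
        region_boxes={
            "anterior": ((2, 5), (2, 5), (3, 6)),
            "posterior": ((7, 10), (2, 5), (3, 6)),
            "ventral": ((2, 5), (7, 10), (3, 6)),
            "wm": ((7, 10), (7, 10), (3, 6)),
            "csf": ((5, 7), (7, 10), (3, 6)),
        },
    )


@dataclass(frozen=True)
class EffectSpec:
    """A planted biomarker-connectivity effect: target metric and correlation."""

    metric: str
    r: float

    def validate(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not abs(self.r) < 1.0:
            raise ValueError(f"effect correlation must satisfy |r| < 1, got {self.r}")


def default_effect_map() -> dict[tuple[str, str], EffectSpec]:
    """The reported significant biomarker-connectivity couplings.

    Positive GAP-43 coupling in CN and negative tau / p-tau couplings in
    MCI, all on the "average to posterior" RV ratio; amyloid-beta carries
    no planted effect in either group.
    """
    return {
        ("CN", "gap43"): EffectSpec("average to posterior", 0.491),
        ("MCI", "ttau"): EffectSpec("average to posterior", -0.590),
        ("MCI", "ptau181"): EffectSpec("average to posterior", -0.582),
    }


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohort.

    ``connectivity_range`` is the support of the per-subject, per-region
    coherence parameter c (uniform draw).  The default (0.3, 0.9) gives
    wide between-subject spread, so individual differences in coherence
    dominate estimation noise — the regime the association analysis
    assumes.  Amplitudes are in units of the (unit-variance) region
    signal.
    """

    n_cn: int = 25
    n_mci: int = 23
    n_timepoints: int = 140
    tr_seconds: float = 3.0
    connectivity_range: tuple[float, float] = (0.3, 0.9)
    effect_map: dict[tuple[str, str], EffectSpec] = field(default_factory=default_effect_map)
    biomarker_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BIOMARKER_MEANS_SDS))
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.3
    compartment_leak: float = 0.3
    band: FilterBand = field(default_factory=FilterBand)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cn <= 0 or self.n_mci <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_timepoints <= 0 or self.tr_seconds <= 0:
            raise ValueError("n_timepoints and tr_seconds must be positive")
        lo, hi = self.connectivity_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("connectivity_range must be strictly inside (0, 1)")
        for (group, biomarker), effect in self.effect_map.items():
            if group not in GROUPS:
                raise ValueError(f"effect_map references unknown group {group!r}")
            if biomarker not in BIOMARKERS:
                raise ValueError(f"effect_map references unknown biomarker {biomarker!r}")
            effect.validate()
        for name in self.biomarker_means_sds:
            if name not in BIOMARKERS:
                raise ValueError(f"unknown biomarker {name!r} in biomarker_means_sds")
        for amp in (self.drift_amplitude, self.motion_amplitude, self.compartment_leak):
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_cn + self.n_mci

    def min_timepoints(self) -> int:
        """Shortest series supporting two cycles of the lowest passband frequency."""
        return int(np.ceil(2.0 / (self.band.low_hz * self.tr_seconds)))

    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_subjects)]

    def groups(self) -> list[str]:
        return ["CN"] * self.n_cn + ["MCI"] * self.n_mci


@dataclass
class LatentTruth:
    """Planted ground truth: per-region coherence c, covariates, raw biomarkers."""

    table: pd.DataFrame

    def connectivity(self, subject_index: int) -> dict[str, float]:
        row = self.table.iloc[subject_index]
        return {region: float(row[f"c_{region}"]) for region in DMN_REGIONS}


def _subject_rng(seed: int, stream: int, subject_index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, subject_index)))


def generate_roi_atlas(spec: AtlasSpec | None = None) -> RoiAtlas:
    """Paint the spec's disjoint boxes into an integer label volume."""
    spec = spec or AtlasSpec()
    spec.validate()
    labels = np.zeros(spec.grid_dims, dtype=np.int32)
    for name, box in spec.region_boxes.items():
        (x0, x1), (y0, y1), (z0, z1) = box
        labels[x0:x1, y0:y1, z0:z1] = spec.label_codes[name]
    return RoiAtlas(labels=labels, code_map=dict(spec.label_codes),
                    voxel_size_mm=spec.voxel_size_mm)


def _band_limited_signal(rng: np.random.Generator, n: int, tr: float,
                         band: FilterBand) -> np.ndarray:
    """Unit-variance white noise filtered into the passband (zero mean)."""
    s = bandpass_array(rng.standard_normal(n), tr, band)
    return s / s.std()


def plant_truth(cohort: CohortSpec) -> LatentTruth:
    """Draw the latent state: coherence parameters and demographic covariates."""
    cohort.validate()
    rng = _subject_rng(cohort.seed, _STREAM_TRUTH)
    rows = []
    groups = cohort.groups()
    lo, hi = cohort.connectivity_range
    # per-group shuffled sex assignment with fixed female counts
    sex_by_group: dict[str, list[int]] = {}
    for group, n in (("CN", cohort.n_cn), ("MCI", cohort.n_mci)):
        n_female = int(round(n * FEMALE_FRACTION[group]))
        sexes = np.array([0] * n_female + [1] * (n - n_female))
        rng.shuffle(sexes)
        sex_by_group[group] = sexes.tolist()
    counters = {g: 0 for g in GROUPS}
    for sid, group in zip(cohort.subject_ids(), groups):
        age_mu, age_sd = AGE_BY_GROUP[group]
        edu_mu, edu_sd = EDUCATION_BY_GROUP[group]
        ceiling, rate, floor = MMSE_BY_GROUP[group]
        row = {
            "subject_id": sid,
            "group": group,
            "age": float(rng.normal(age_mu, age_sd)),
            "sex": sex_by_group[group][counters[group]],
            "education": int(np.clip(round(rng.normal(edu_mu, edu_sd)), 6, 22)),
            "mmse": int(np.clip(ceiling - rng.poisson(rate), floor, 30)),
        }
        counters[group] += 1
        for region in DMN_REGIONS:
            row[f"c_{region}"] = float(rng.uniform(lo, hi))
        rows.append(row)
    return LatentTruth(table=pd.DataFrame(rows))


def generate_bold(subject_index: int, atlas: RoiAtlas, cohort: CohortSpec,
                  truth: LatentTruth) -> tuple[BoldSeries, NuisanceSet]:
    """One subject's contaminated 4D BOLD series plus the exact motion used.

    Deterministic in (cohort.seed, subject_index): regenerating the same
    subject yields bit-identical volumes regardless of cohort ordering.
    """
    cohort.validate()
    t = cohort.n_timepoints
    if t < cohort.min_timepoints():
        raise ValueError(
            f"n_timepoints={t} too short for the {cohort.band.low_hz} Hz band at "
            f"TR={cohort.tr_seconds}s; need at least {cohort.min_timepoints()} volumes")
    rng = _subject_rng(cohort.seed, _STREAM_BOLD, subject_index)
    c_by_region = truth.connectivity(subject_index)

    data = rng.standard_normal(atlas.labels.shape + (t,))
    for region in DMN_REGIONS:
        c = c_by_region[region]
        s = _band_limited_signal(rng, t, cohort.tr_seconds, cohort.band)
        mask = atlas.region_mask(region)
        data[mask] = np.sqrt(c) * s + np.sqrt(1.0 - c) * data[mask]
    comp_signals = {}
    for comp in COMPARTMENTS:
        u = _band_limited_signal(rng, t, cohort.tr_seconds, cohort.band)
        comp_signals[comp] = u
        mask = atlas.region_mask(comp)
        data[mask] = u + 0.3 * data[mask]

    # linear drift: per-voxel random slope over normalized scan time
    ramp = np.linspace(-0.5, 0.5, t)
    slopes = rng.normal(0.0, 1.0, atlas.labels.shape)
    data += cohort.drift_amplitude * slopes[..., None] * ramp

    # six motion-like regressors: standardized random walks, shared loadings
    steps = rng.standard_normal((t, 6))
    motion = np.cumsum(steps, axis=0)
    motion = (motion - motion.mean(axis=0)) / motion.std(axis=0)
    loadings = rng.normal(0.0, 1.0, atlas.labels.shape + (6,)) / np.sqrt(6.0)
    data += cohort.motion_amplitude * np.einsum("xyzk,tk->xyzt", loadings, motion)

    # WM/CSF signal leakage into every voxel
    if cohort.compartment_leak > 0:
        for comp in COMPARTMENTS:
            w = rng.normal(0.0, 1.0, atlas.labels.shape)
            data += cohort.compartment_leak * w[..., None] * comp_signals[comp]

    series = BoldSeries(data=data, tr_seconds=cohort.tr_seconds,
                        voxel_size_mm=(atlas.voxel_size_mm,) * 3)
    nuisance = NuisanceSet(motion=motion, wm_pcs=np.empty((t, 0)),
                           csf_pcs=np.empty((t, 0)))
    return series, nuisance


def asymptotic_rv(name: str, c_by_region: dict[str, np.ndarray]) -> np.ndarray:
    """Noise-free RV value implied by the planted coherences, per subject.

    In the limit of long series and many voxels, the correlation of a
    voxel in region R with its own region mean is sqrt(c_R), and with the
    mean of an equal-sized-region union it is c_R / sqrt(sum of the
    union's c values); the RV is the median Fisher-z over the voxel set.
    Equal region sizes (true of the shipped atlas geometries) are assumed.
    """
    if name in DMN_REGIONS:
        return np.arctanh(np.sqrt(c_by_region[name]))
    if name == "average":
        members = DMN_REGIONS
    elif name == "anterior-posterior":
        members = ("anterior", "posterior")
    else:
        raise ValueError(f"unknown region {name!r}")
    cs = np.stack([np.asarray(c_by_region[r], dtype=float) for r in members])
    z = np.arctanh(cs / np.sqrt(cs.sum(axis=0)))
    return np.median(z, axis=0)


def effect_driver(metric: str, group_truth: pd.DataFrame) -> np.ndarray:
    """Latent quantity a planted effect couples to, per subject.

    The driver is the metric's model-implied (asymptotic, noise-free)
    value as a function of the planted coherence parameters: the
    asymptotic RV for "Median X" metrics and the ratio of asymptotic RVs
    for "X to Y" metrics.  Coupling biomarkers to this truth-side quantity
    means measured associations are attenuated only by measurement noise.
    """
    c = {r: group_truth[f"c_{r}"].to_numpy() for r in DMN_REGIONS}
    if metric in MEDIAN_METRICS:
        return asymptotic_rv(metric.removeprefix("Median "), c)
    for a, b in RATIO_PAIRS:
        if metric == f"{a} to {b}":
            return asymptotic_rv(a, c) / asymptotic_rv(b, c)
    raise ValueError(f"unknown metric {metric!r}")


def generate_phenotypes(cohort: CohortSpec, truth: LatentTruth) -> pd.DataFrame:
    """Phenotype table with biomarkers coupled to the planted connectivity.

    For effect r on metric M in group g, a subject's standardized biomarker
    is ``r * z + sqrt(1 - r^2) * eta`` where z is the group-standardized
    effect driver of M and eta is iid standard normal; the result is mapped
    to pg/mL via the per-biomarker location/scale.  Unrounded values are
    written back into the truth table (``<biomarker>_raw`` columns).
    """
    cohort.validate()
    rng = _subject_rng(cohort.seed, _STREAM_PHENO)
    table = truth.table
    n = len(table)
    if n != cohort.n_subjects:
        raise ValueError("truth table does not match the cohort size")
    pheno = table[["subject_id", "group", "age", "sex", "education", "mmse"]].copy()
    for biomarker in BIOMARKERS:
        mean, sd = cohort.biomarker_means_sds.get(biomarker, BIOMARKER_MEANS_SDS[biomarker])
        values = np.empty(n)
        eta = rng.standard_normal(n)
        for group in GROUPS:
            idx = (table["group"] == group).to_numpy()
            effect = cohort.effect_map.get((group, biomarker))
            r = effect.r if effect is not None else 0.0
            if effect is not None and idx.sum() >= 2:
                d = effect_driver(effect.metric, table.loc[idx])
                z = (d - d.mean()) / d.std() if d.std() > 0 else np.zeros(idx.sum())
            else:
                z = np.zeros(int(idx.sum()))
            values[idx] = r * z + np.sqrt(1.0 - r ** 2) * eta[idx]
        levels = mean + sd * values
        levels = np.maximum(levels, 1.0)  # biomarker concentrations are positive
        truth.table[f"{biomarker}_raw"] = levels
        pheno[biomarker] = np.round(levels, 1)
    pheno["age"] = np.round(pheno["age"], 1)
    return pheno


@dataclass
class SimulatedCohort:
    """In-memory bundle of everything one simulation run produces."""

    cohort: CohortSpec
    atlas: RoiAtlas
    subjects: list[tuple[str, BoldSeries, NuisanceSet]]
    phenotypes: pd.DataFrame
    truth: LatentTruth


def simulate_cohort(cohort: CohortSpec,
                    atlas_spec: AtlasSpec | None = None) -> SimulatedCohort:
    """Generate atlas, per-subject BOLD + nuisance, phenotypes, and truth."""
    atlas_spec = atlas_spec or AtlasSpec()
    atlas = generate_roi_atlas(atlas_spec)
    truth = plant_truth(cohort)
    phenotypes = generate_phenotypes(cohort, truth)
    subjects = []
    for i, sid in enumerate(cohort.subject_ids()):
        series, nuisance = generate_bold(i, atlas, cohort, truth)
        subjects.append((sid, series, nuisance))
    return SimulatedCohort(cohort=cohort, atlas=atlas, subjects=subjects,
                           phenotypes=phenotypes, truth=truth)


def write_fixture_set(atlas: RoiAtlas, subjects, phenotypes: pd.DataFrame,
                      out_dir, truth: LatentTruth | None = None) -> dict:
    """Write a complete fixture set and return its manifest.

    One 4D NIfTI and one motion-regressor text file per subject, a 3D atlas
    NIfTI, phenotypes and (optionally) latent truth as CSV, and a JSON
    manifest.  Re-reading any written series reproduces the array exactly.
    """
    if not subjects:
        raise ValueError("empty series list: nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    subject_ids = []
    for sid, series, nuisance in subjects:
        bold_path = out / f"{sid}_bold.nii.gz"
        save_series(series, bold_path)
        motion_path = out / f"{sid}_motion.txt"
        np.savetxt(motion_path, nuisance.motion, fmt="%.10g")
        files[f"{sid}_bold"] = bold_path.name
        files[f"{sid}_motion"] = motion_path.name
        subject_ids.append(sid)
    atlas_path = out / "atlas.nii.gz"
    save_atlas(atlas, atlas_path)
    files["atlas"] = atlas_path.name
    pheno_path = out / "phenotypes.csv"
    phenotypes.to_csv(pheno_path, index=False)
    files["phenotypes"] = pheno_path.name
    if truth is not None:
        truth_path = out / "truth.csv"
        truth.table.to_csv(truth_path, index=False)
        files["truth"] = truth_path.name
    manifest = {"n_subjects": len(subjects), "subject_ids": subject_ids, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
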