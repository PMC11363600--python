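"""End-to-end orchestration: simulate -> preprocess -> connectivity -> associate.

A single :class:`RunConfig` (YAML- or JSON-serializable) drives all four
stages; every stage writes its outputs plus a small manifest recording the
hash of the configuration it ran under and of the files it produced, so a
re-run skips stages whose manifests still match (deleting one stage's
outputs recomputes only that stage).  All randomness flows from the single
seed, fanned out to per-subject substreams, so a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import compute_metric_table, metrics_to_frame
from .core import load_atlas, load_series, save_series
from .preprocess import DEFAULT_BAND, FilterBand, PreprocParams, preprocess_subject
from .stats import build_association_tables
from .synthetic import (AtlasSpec, CohortSpec, EffectSpec, simulate_cohort,
                        write_fixture_set)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable and round-trippable."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    metric_mode: str = "ratio"        # "ratio" | "timecourse" reading of "X to Y"
    fdr_family: str = "column"        # "column" | "table"
    alpha: float = 0.05
    out_dir: str = "dmnrv_run"
    seed: int = 0

    def __post_init__(self) -> None:
        # the top-level seed is authoritative
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["effect_map"] = [
            {"group": g, "biomarker": b, "metric": e.metric, "r": e.r}
            for (g, b), e in self.cohort.effect_map.items()]
        d["cohort"]["connectivity_range"] = list(self.cohort.connectivity_range)
        d["cohort"]["band"] = [self.cohort.band.low_hz, self.cohort.band.high_hz]
        d["atlas"]["grid_dims"] = list(self.atlas.grid_dims)
        d["atlas"]["region_boxes"] = {
            name: [list(iv) for iv in box]
            for name, box in self.atlas.region_boxes.items()}
        d["preproc"]["band"] = [self.preproc.band.low_hz, self.preproc.band.high_hz]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "effect_map" in c:
                c["effect_map"] = {
                    (e["group"], e["biomarker"]): EffectSpec(e["metric"], e["r"])
                    for e in c["effect_map"]}
            if "connectivity_range" in c:
                c["connectivity_range"] = tuple(c["connectivity_range"])
            if "band" in c:
                c["band"] = FilterBand(*c["band"])
            if "biomarker_means_sds" in c:
                c["biomarker_means_sds"] = {
                    k: tuple(v) for k, v in c["biomarker_means_sds"].items()}
            d["cohort"] = CohortSpec(**c)
        if "atlas" in d:
            a = dict(d["atlas"])
            if "grid_dims" in a:
                a["grid_dims"] = tuple(a["grid_dims"])
            if "region_boxes" in a:
                a["region_boxes"] = {
                    name: tuple(tuple(iv) for iv in box)
                    for name, box in a["region_boxes"].items()}
            d["atlas"] = AtlasSpec(**a)
        if "preproc" in d:
            p = dict(d["preproc"])
            if "band" in p:
                p["band"] = FilterBand(*p["band"])
            d["preproc"] = PreprocParams(**p)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


def validate_config(config: RunConfig) -> tuple[RunConfig, list[str]]:
    """Check ranges, normalize, and flag convention-divergent choices."""
    errors: list[str] = []
    warnings: list[str] = []
    try:
        config.cohort.validate()
    except ValueError as exc:
        errors.append(str(exc))
    try:
        config.atlas.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if config.metric_mode not in ("ratio", "timecourse"):
        errors.append(f"metric_mode must be 'ratio' or 'timecourse', got {config.metric_mode!r}")
    if config.fdr_family not in ("column", "table"):
        errors.append(f"fdr_family must be 'column' or 'table', got {config.fdr_family!r}")
    if not (0 < config.alpha < 1):
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.preproc.discard_k < 0:
        errors.append("discard_k must be non-negative")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    band = (config.preproc.band.low_hz, config.preproc.band.high_hz)
    if band != DEFAULT_BAND:
        warnings.append(
            f"passband {band} Hz differs from the reference 0.01-0.08 Hz range")
    if config.preproc.discard_k != 3:
        warnings.append(
            f"discard_k={config.preproc.discard_k} differs from the reference "
            "(the initial 3 volumes are conventionally discarded)")
    if config.preproc.fwhm_mm != 4.0:
        warnings.append(
            f"fwhm_mm={config.preproc.fwhm_mm} differs from the reference 4 mm kernel")
    if (config.cohort.n_cn, config.cohort.n_mci) != (25, 23):
        warnings.append(
            f"group sizes ({config.cohort.n_cn}, {config.cohort.n_mci}) differ "
            "from the reference cohort (CN n=25, MCI n=23)")
    for w in warnings:
        logger.warning("%s", w)
    return config, warnings


# ---------------------------------------------------------------------------
# stage plumbing

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_manifest_path(out: Path, stage: str) -> Path:
    return out / f".stage_{stage}.json"


def _stage_fresh(out: Path, stage: str, config_hash: str) -> bool:
    """True if the stage's previous outputs are intact under this config."""
    mpath = _stage_manifest_path(out, stage)
    if not mpath.exists():
        return False
    manifest = json.loads(mpath.read_text())
    if manifest.get("config_hash") != config_hash:
        return False
    for rel, digest in manifest.get("outputs", {}).items():
        f = out / rel
        if not f.exists() or _sha256(f) != digest:
            return False
    return True


def _record_stage(out: Path, stage: str, config_hash: str,
                  outputs: list[Path], seconds: float) -> dict:
    manifest = {
        "stage": stage,
        "config_hash": config_hash,
        "seconds": round(seconds, 3),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    _stage_manifest_path(out, stage).write_text(json.dumps(manifest, indent=2))
    return manifest


@dataclass
class RunReport:
    """Run summary: per-stage manifests, warnings, and recovery diagnostics."""

    config: dict
    stages: dict[str, dict]
    warnings: list[str]
    recovery: dict[str, float] | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def run_pipeline(config: RunConfig, input_dir=None) -> RunReport:
    """Execute all four stages (or start from existing fixtures).

    ``input_dir`` may point at a fixture directory (atlas.nii.gz,
    ``*_bold.nii.gz``, ``*_motion.txt``, phenotypes.csv) to skip
    simulation — the entry point for spatially aligned real data.
    """
    config, warnings = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    stages: dict[str, dict] = {}

    # -- stage 1: simulate -------------------------------------------------
    fixtures = Path(input_dir) if input_dir else out / "fixtures"
    if input_dir is None:
        if _stage_fresh(out, "simulate", chash):
            logger.info("simulate: outputs fresh, skipping")
            stages["simulate"] = json.loads(_stage_manifest_path(out, "simulate").read_text())
        else:
            t0 = time.perf_counter()
            sim = simulate_cohort(config.cohort, config.atlas)
            manifest = write_fixture_set(sim.atlas, sim.subjects, sim.phenotypes,
                                         fixtures, truth=sim.truth)
            outputs = [fixtures / name for name in manifest["files"].values()]
            outputs.append(fixtures / "manifest.json")
            stages["simulate"] = _record_stage(out, "simulate", chash, outputs,
                                               time.perf_counter() - t0)
    atlas_path = fixtures / "atlas.nii.gz"
    pheno_path = fixtures / "phenotypes.csv"
    for required, label in ((atlas_path, "atlas"), (pheno_path, "phenotype table")):
        if not required.exists():
            raise FileNotFoundError(f"missing input: no {label} at {required}")
    atlas = load_atlas(atlas_path)
    bold_paths = sorted(fixtures.glob("*_bold.nii.gz"))
    if not bold_paths:
        raise FileNotFoundError(f"missing input: no *_bold.nii.gz under {fixtures}")

    # -- stage 2: preprocess ----------------------------------------------
    prep_dir = out / "preprocessed"
    if _stage_fresh(out, "preprocess", chash):
        logger.info("preprocess: outputs fresh, skipping")
        stages["preprocess"] = json.loads(_stage_manifest_path(out, "preprocess").read_text())
    else:
        t0 = time.perf_counter()
        prep_dir.mkdir(exist_ok=True)
        outputs = []
        for bold_path in bold_paths:
            sid = bold_path.name.removesuffix("_bold.nii.gz")
            series = load_series(bold_path)
            motion_path = fixtures / f"{sid}_motion.txt"
            motion = np.loadtxt(motion_path) if motion_path.exists() else None
            clean = preprocess_subject(series, atlas, motion, config.preproc)
            dest = prep_dir / f"{sid}_clean.nii.gz"
            save_series(clean, dest)
            outputs.append(dest)
        stages["preprocess"] = _record_stage(out, "preprocess", chash, outputs,
                                             time.perf_counter() - t0)

    # -- stage 3: connectivity --------------------------------------------
    metrics_path = out / "metrics.csv"
    if _stage_fresh(out, "connectivity", chash):
        logger.info("connectivity: outputs fresh, skipping")
        stages["connectivity"] = json.loads(
            _stage_manifest_path(out, "connectivity").read_text())
    else:
        t0 = time.perf_counter()
        by_subject = {}
        for clean_path in sorted(prep_dir.glob("*_clean.nii.gz")):
            sid = clean_path.name.removesuffix("_clean.nii.gz")
            series = load_series(clean_path)
            by_subject[sid] = compute_metric_table(series, atlas, mode=config.metric_mode)
        metrics_to_frame(by_subject).to_csv(metrics_path)
        stages["connectivity"] = _record_stage(out, "connectivity", chash,
                                               [metrics_path], time.perf_counter() - t0)

    # -- stage 4: associate -------------------------------------------------
    if _stage_fresh(out, "associate", chash):
        logger.info("associate: outputs fresh, skipping")
        stages["associate"] = json.loads(_stage_manifest_path(out, "associate").read_text())
    else:
        t0 = time.perf_counter()
        metrics = pd.read_csv(metrics_path, index_col="subject_id")
        pheno = pd.read_csv(pheno_path)
        records, tables = build_association_tables(
            metrics, pheno, alpha=config.alpha, fdr_family=config.fdr_family)
        outputs = []
        for name, table in tables.items():
            dest = out / f"{name}.csv"
            table.to_csv(dest)
            outputs.append(dest)
        rec_path = out / "associations.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(rec_path, index=False)
        outputs.append(rec_path)
        decisions = {
            "fdr_family": config.fdr_family,
            "alpha": config.alpha,
            "metric_mode": config.metric_mode,
            "n_subjects": int(len(pheno)),
        }
        dec_path = out / "decisions.json"
        dec_path.write_text(json.dumps(decisions, indent=2))
        outputs.append(dec_path)
        stages["associate"] = _record_stage(out, "associate", chash, outputs,
                                            time.perf_counter() - t0)

    # -- truth-vs-estimate recovery summary (synthetic runs only) ----------
    recovery = None
    truth_path = fixtures / "truth.csv"
    if truth_path.exists() and metrics_path.exists():
        truth = pd.read_csv(truth_path)
        metrics = pd.read_csv(metrics_path, index_col="subject_id")
        joined = truth.set_index("subject_id").join(metrics, how="inner")
        recovery = {}
        for region, metric in (("posterior", "Median posterior"),
                               ("ventral", "Median ventral")):
            if len(joined) >= 3:
                recovery[f"corr_c_{region}_vs_{metric}"] = float(
                    np.corrcoef(joined[f"c_{region}"], joined[metric])[0, 1])

    report = RunReport(config=config.to_dict(), stages=stages,
                       warnings=warnings, recovery=recovery)
    report.to_json(out / "report.json")
    return report
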