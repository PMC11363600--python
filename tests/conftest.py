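"""Shared fixtures: tiny atlases, cohorts, and random BOLD builders."""

import numpy as np
import pandas as pd
import pytest

from dmnrv.core import BoldSeries, RoiAtlas
from dmnrv.synthetic import (CohortSpec, LatentTruth, compact_atlas_spec,
                             generate_roi_atlas)


@pytest.fixture
def rng():
    return np.random.default_rng(20240830)


@pytest.fixture
def compact_atlas():
    return generate_roi_atlas(compact_atlas_spec())


@pytest.fixture
def tiny_cohort():
    """A small, fast cohort: 4 CN + 3 MCI subjects, 80 volumes."""
    return CohortSpec(n_cn=4, n_mci=3, n_timepoints=80, seed=11)


def make_micro_atlas():
    """A 6x6x4 atlas with 24-voxel regions, used for oracle comparisons."""
    labels = np.zeros((6, 6, 4), dtype=np.int32)
    labels[0:2, 0:3, :] = 1   # anterior
    labels[2:4, 0:3, :] = 2   # posterior
    labels[4:6, 0:3, :] = 3   # ventral
    labels[0:3, 3:6, :] = 4   # wm
    labels[3:6, 3:6, :] = 5   # csf
    return RoiAtlas(labels=labels, code_map={
        "anterior": 1, "posterior": 2, "ventral": 3, "wm": 4, "csf": 5})


def random_subject(rng, atlas=None, t=60, tr=2.0):
    """Pure-noise BOLD series on the micro atlas grid."""
    atlas = atlas or make_micro_atlas()
    data = rng.standard_normal(atlas.labels.shape + (t,))
    return BoldSeries(data=data, tr_seconds=tr), atlas


def truth_with_constant_c(cohort: CohortSpec, c: float) -> LatentTruth:
    """Latent truth where every subject and region has coherence ``c``."""
    from dmnrv.synthetic import plant_truth

    truth = plant_truth(cohort)
    for region in ("anterior", "posterior", "ventral"):
        truth.table[f"c_{region}"] = c
    return truth
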