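"""Shared fixtures: small grids, synthetic cohorts, and the null-calibration
study reused by the cluster-inference and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from fagap.clusters import analyze_clusters
from fagap.contrast import contrast
from fagap.core import FAVolume, TierConfig
from fagap.synthetic import PlantedEffect, SimConfig, generate_cohort

N_NULL_SEEDS = 100


def make_volume(data, subject_id="s", affine=None):
    return FAVolume(data=np.asarray(data, dtype=float),
                    affine=np.eye(4) if affine is None else affine,
                    subject_id=subject_id)


def volumes_from_values(values_a, values_b, shape=(4, 4, 4), voxel=(1, 1, 1)):
    """Two groups of constant volumes differing only at one voxel."""
    group_a, group_b = [], []
    for i, v in enumerate(values_a):
        d = np.full(shape, 0.5)
        d[voxel] = v
        group_a.append(make_volume(d, f"a{i}"))
    for i, v in enumerate(values_b):
        d = np.full(shape, 0.5)
        d[voxel] = v
        group_b.append(make_volume(d, f"b{i}"))
    return group_a, group_b


@pytest.fixture(scope="session")
def bimodal_config():
    """Study conditions for the subgroup-recovery scenario: 22 matched pairs,
    a region whose FA is elevated 4 post-smoothing s.d. in 10 of 22 patients,
    and a second region reduced 2 s.d. in the complementary 12."""
    return SimConfig(
        n_pairs=22,
        effects=[
            PlantedEffect(box=((12, 17), (12, 17), (12, 17)),
                          direction="increase", effect_size=0.0,
                          subgroup_fraction=10 / 22, separation=4.0,
                          name="vta"),
            PlantedEffect(box=((22, 27), (8, 13), (20, 25)),
                          direction="decrease", effect_size=0.0,
                          separation=2.0, complement_of="vta", name="mfb"),
        ],
        seed=20_260_925,
    )


@pytest.fixture(scope="session")
def bimodal_cohort(bimodal_config):
    return generate_cohort(bimodal_config)


@pytest.fixture(scope="session")
def null_study():
    """Per-seed cluster tables from 22v22 cohorts with no planted effect.

    Returns a list (one entry per seed) of analyzed cluster lists; used to
    check the family-wise false-positive rate of the tiered correction.
    """
    config = TierConfig()
    out = []
    for seed in range(N_NULL_SEEDS):
        sim = generate_cohort(SimConfig(n_pairs=22, effects=[], seed=seed))
        sm = contrast(sim.patients, sim.controls)
        out.append(analyze_clusters(sm, sim.aoes, config))
    return out
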