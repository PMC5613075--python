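"""Shared fixtures.

The expensive pieces — the default synthetic study and the evolved models
for each feature mode / sensor channel — are session-scoped so the whole
suite trains each configuration exactly once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import caldera as cd
from caldera.evolution import FeatureMode


#: Training protocol used for the headline surrogate and mode comparisons:
#: 10 independent runs at population 50 / 40 generations, seeds 1..10.
RUN_SEEDS = list(range(1, 11))
RUN_CONFIG = dict(population_size=50, generations=40)


@pytest.fixture(scope="session")
def default_study():
    """The default seeded synthetic study (seed 42)."""
    return cd.generate_study(cd.SyntheticConfig())


@pytest.fixture(scope="session")
def small_study():
    """A miniature study for cheap structural tests."""
    counts = {
        split: {"rest": 3, "walking": 3, "voluntary": 2,
                "dyskinesia_3": 3, "dyskinesia_4": 3}
        for split in ("train", "test", "holdout")
    }
    cfg = dataclasses.replace(
        cd.SyntheticConfig(), counts=counts, fractional_grade_fraction=0.0, seed=7
    )
    return cd.generate_study(cfg)


@pytest.fixture(scope="session")
def feature_sets(default_study):
    """Prepared train/test/holdout TrainingSets per (mode, channel)."""
    out = {}
    for mode, chan in [
        (FeatureMode.TIME, "accel"),
        (FeatureMode.SPECTRAL_LONG, "accel"),
        (FeatureMode.SPECTRAL_SHORT, "accel"),
        (FeatureMode.TIME, "gyro"),
    ]:
        out[(mode, chan)] = {
            split: cd.build_training_set(
                cd.items_from_study(default_study, split, chan), mode
            )
            for split in ("train", "test", "holdout")
        }
    return out


@pytest.fixture(scope="session")
def trained_models(feature_sets):
    """Best-of-10-runs models per (mode, channel) on the default study."""
    out = {}
    for key, sets in feature_sets.items():
        mode, _chan = key
        cfg = cd.EvolutionConfig(feature_mode=mode, **RUN_CONFIG)
        model, results = cd.multi_run_select(
            cfg, sets["train"], sets["test"], len(RUN_SEEDS), RUN_SEEDS
        )
        out[key] = (model, results)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_genome(placed_nodes, output_gene, geometry=None):
    """Hand-build a genome from (node_index, function_name, in_a, in_b)
    entries; unused nodes default to ('add', 0, 0).

    Remember the grid is column-major with 6 rows: node j sits in column
    j // 6 and may only read terminals or nodes from earlier columns, so
    chains must hop columns (e.g. indices 0, 6, 12).  Node j is addressed
    as source 32 + j.
    """
    geometry = geometry or cd.CgpGeometry()
    from caldera.cgp import FUNCTION_NAMES

    arr = np.zeros((geometry.n_nodes, 3), dtype=np.int64)
    for j, fname, a, b in placed_nodes:
        arr[j] = [FUNCTION_NAMES.index(fname), a, b]
    g = cd.CgpGenome(arr, output_gene, geometry)
    g.validate()
    return g
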