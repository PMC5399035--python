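"""Shared fixtures: desk-scale geometry and a small synthetic cohort.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from alphasync.synthetic import default_spec, generate_cohort, toy_geometry


@pytest.fixture(scope="session")
def geometry():
    """(sensor_pos, sensor_ori, source_pos, source_ori, labels, atlas)."""
    return toy_geometry(n_sensors=48, n_sources_per_area=2)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny but complete cohort spec: 5/5/5 subjects, 250 Hz, 12 epochs."""
    return default_spec(n_subjects_per_group={"HC": 5, "SCD": 5, "MCI": 5},
                        rate=250.0, n_epochs_mean=12, seed=7,
                        n_sensors=48, n_sources_per_area=2)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    subjects, report = generate_cohort(small_spec)
    return subjects, report


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
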