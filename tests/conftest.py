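"""Shared fixtures: tiny label volumes and the planted-rule phantom cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from koosgrade import FeatureTable, generate_cohort
from koosgrade.features import FEATURE_COLUMNS, feature_name
from koosgrade.phantom import PlantedRule
from koosgrade.pipeline import cohort_feature_tables
from koosgrade.schemes import (
    BRAINSTEM,
    IPSI_CEREBELLUM,
    VS,
    canonical_scheme,
)

COHORT_SEED = 1234  # the study cohort: n = 200, equal grade mix, zero noise
COHORT_N = 200


def make_label_volume(voxels, spacing=1.0, scheme=None, origin=(0.0, 0.0, 0.0)):
    from koosgrade import LabelVolume

    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    return LabelVolume(np.asarray(voxels, dtype=np.int32), affine, scheme=scheme)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(COHORT_N, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_tables(cohort):
    tables, quarantined = cohort_feature_tables(cohort)
    assert not quarantined
    return tables


@pytest.fixture(scope="session")
def cohort_table(cohort_tables):
    """Combined-modality feature table of the study cohort."""
    return cohort_tables["ceT1+hrT2"]


def planted_feature_frame(
    n: int, seed: int, n_noise: int = 0, rule: PlantedRule = PlantedRule()
) -> FeatureTable:
    """Tabular planted-rule data: canonical predictors sampled directly.

    Volumes, brainstem/cerebellum distances and contact areas are drawn
    so that every grade region of the planted rule is populated; noise
    predictors are uninformative uniforms.  Much faster than digitizing
    phantoms when only the classifier is under test.
    """
    rng = np.random.default_rng(seed)
    grades = rng.integers(1, 5, size=n)
    vol = np.empty(n)
    d_bs = np.empty(n)
    d_cb = np.empty(n)
    contact = np.empty(n)
    for i, g in enumerate(grades):
        if g == 4:
            vol[i] = rng.uniform(rule.volume_iv_mm3, 6000)
            d_bs[i] = rng.uniform(0.8, rule.touch_mm)
            d_cb[i] = 0.8
            contact[i] = rng.uniform(300, 900)
        elif g == 3:
            vol[i] = rng.uniform(800, rule.volume_iv_mm3 - 100)
            d_bs[i] = rng.uniform(0.8, rule.touch_mm)
            d_cb[i] = 0.8
            contact[i] = rng.uniform(100, 600)
        elif g == 2:
            vol[i] = rng.uniform(250, 1500)
            d_bs[i] = rng.uniform(3.0, 10.0)
            d_cb[i] = 0.8
            contact[i] = rng.uniform(50, 400)
        else:
            vol[i] = rng.uniform(30, 200)
            d_bs[i] = rng.uniform(8.0, 20.0)
            d_cb[i] = rng.uniform(2.5, 6.0)
            contact[i] = 0.0
    df = pd.DataFrame(0.0, index=[f"t{i:04d}" for i in range(n)], columns=list(FEATURE_COLUMNS))
    df[feature_name("volume", VS)] = vol
    df[feature_name("distance_to_vs", BRAINSTEM)] = d_bs
    df[feature_name("distance_to_vs", IPSI_CEREBELLUM)] = d_cb
    df[feature_name("contact_area_with_vs", IPSI_CEREBELLUM)] = contact
    # the remaining canonical distance columns: mildly grade-correlated filler
    for col in FEATURE_COLUMNS:
        if (df[col] == 0).all() and "distance" in col:
            df[col] = rng.uniform(5, 30, size=n)
    for j in range(n_noise):
        df[f"noise_{j:02d}"] = rng.uniform(0, 1, size=n)
    df.index.name = "case_id"
    return FeatureTable(df, pd.Series(grades, index=df.index, name="koos_grade"))


@pytest.fixture
def separable_volumes():
    """Perfectly separable baseline toy: grade bands 1,2 | 11,12 | 21,22 | 31,32."""
    volumes = np.array([1.0, 2.0, 11.0, 12.0, 21.0, 22.0, 31.0, 32.0])
    grades = np.array([1, 1, 2, 2, 3, 3, 4, 4])
    return volumes, grades


@pytest.fixture
def canonical():
    return canonical_scheme()
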