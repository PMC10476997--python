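"""Shared fixtures: model parameter sets, tiny influence instances, and the
session-scoped water-phantom studies reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from rowdplan.grids import VoxelGrid
from rowdplan.influence import InfluenceData
from rowdplan.phantom import PhantomSpec, make_water_phantom
from rowdplan.radiobio import OERModelParams, TARGET_TISSUE
from rowdplan.workflows import phantom_fields, run_phantom_study
from rowdplan.beam import init_sobp_plan
from scipy import sparse


@pytest.fixture(scope="session")
def oer_defaults() -> OERModelParams:
    return OERModelParams()


@pytest.fixture(scope="session")
def target_tissue():
    return TARGET_TISSUE


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_influence(rng: np.random.Generator, n_vox: int = 10, n_spots: int = 5):
    """Small dense-backed random influence instance for oracle comparisons."""
    d = rng.uniform(0.0, 1.0, size=(n_vox, n_spots))
    d[rng.uniform(size=d.shape) < 0.3] = 0.0
    let = rng.uniform(1.0, 12.0, size=(n_vox, n_spots))
    n = let * d
    shape = (n_vox, 1, 1)
    return (
        InfluenceData(sparse.csr_matrix(d), sparse.csr_matrix(n), shape),
        d,
        let,
    )


@pytest.fixture()
def small_influence(rng):
    return random_influence(rng)


@pytest.fixture(scope="session")
def mini_phantom_spec() -> PhantomSpec:
    """A scaled-down symmetric phantom for fast optimizer tests."""
    return PhantomSpec(
        shape=(16, 16, 40),
        target_size_mm=16.0,
        target_depth_mm=32.0,
    )


@pytest.fixture(scope="session")
def water_phantom():
    return make_water_phantom()


@pytest.fixture(scope="session")
def single_init(water_phantom):
    return init_sobp_plan(water_phantom.target_mask, phantom_fields("single"), 2.0)


@pytest.fixture(scope="session")
def opposing_init(water_phantom):
    return init_sobp_plan(water_phantom.target_mask, phantom_fields("opposing"), 2.0)


def _study(water_phantom, init_result, fields_kind, model_name):
    return run_phantom_study(
        fields_kind=fields_kind,
        model_name=model_name,
        phantom=water_phantom,
        init_result=init_result,
    )


@pytest.fixture(scope="session")
def study_single_rbe11_oer(water_phantom, single_init):
    return _study(water_phantom, single_init, "single", "rbe11_oer")


@pytest.fixture(scope="session")
def study_opposing_rbe11_oer(water_phantom, opposing_init):
    return _study(water_phantom, opposing_init, "opposing", "rbe11_oer")


@pytest.fixture(scope="session")
def study_single_ror_oer(water_phantom, single_init):
    return _study(water_phantom, single_init, "single", "ror_oer")


@pytest.fixture(scope="session")
def study_opposing_ror_oer(water_phantom, opposing_init):
    return _study(water_phantom, opposing_init, "opposing", "ror_oer")
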