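"""Shared fixtures: all test data is generated in-process, nothing on disk."""

from __future__ import annotations

import numpy as np
import pytest

from cestlab.bm_simulator import (CestVolume, SequenceParams,
                                  simulate_dataset, symmetric_offsets)
from cestlab.fixtures import FixtureSpec, ladder_rois, make_fixture
from cestlab.phantom_geometry import (WATER_PROTON_MM, PoolParams,
                                      Table1Ranges, sample_label_map,
                                      sample_pool_maps)


@pytest.fixture(scope="session")
def water_pool() -> PoolParams:
    return PoolParams(t1_s=1.5, t2_ms=100.0, delta_ppm=0.0, k_hz=0.0,
                      conc_mM=WATER_PROTON_MM)


@pytest.fixture(scope="session")
def creatine_pool() -> PoolParams:
    return PoolParams(t1_s=1.2, t2_ms=10.0, delta_ppm=1.9, k_hz=200.0,
                      conc_mM=150.0)


@pytest.fixture(scope="session")
def short_seq() -> SequenceParams:
    return SequenceParams(b1_uT=1.0, tp_ms=100.0, td_ms=100.0, n_pulses=10,
                          offsets_ppm=symmetric_offsets(4.0, 25))


@pytest.fixture(scope="session")
def ladder32():
    clean, noisy, truth = make_fixture(
        FixtureSpec("creatine-ladder", grid=(32, 32), dyn=25, sigma=0.05,
                    seed=3))
    return clean, noisy, truth


@pytest.fixture(scope="session")
def ladder_rois32():
    return ladder_rois((32, 32))


@pytest.fixture(scope="session")
def rank1_32():
    clean, noisy, _ = make_fixture(
        FixtureSpec("rank1-spectral", grid=(32, 32), dyn=25, sigma=0.05,
                    seed=3))
    return clean, noisy


@pytest.fixture(scope="session")
def small_phantom_vol() -> CestVolume:
    """One random 24x24, 50-offset phantom volume (shared, read-only)."""
    lm = sample_label_map(11, (24, 24), 6)
    pm = sample_pool_maps(lm, Table1Ranges(), 12)
    seq = SequenceParams(b1_uT=1.0, tp_ms=60.0, td_ms=60.0, n_pulses=8,
                         offsets_ppm=symmetric_offsets(5.0, 50))
    return simulate_dataset(pm, seq)


@pytest.fixture()
def unit_volume() -> CestVolume:
    """Constant bright image stack used for closed-form noise checks."""
    h = w = 100
    dyn = 4
    return CestVolume(data=np.ones((h, w, dyn)),
                      offsets_ppm=symmetric_offsets(4.0, dyn),
                      m0=np.ones((h, w)), mask=np.ones((h, w), dtype=bool))
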