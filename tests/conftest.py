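import numpy as np
import pytest

from epiallele.core import GenomicInterval
from epiallele.readlevel import ReadCalls
from epiallele.simulate import (
    ReadModel,
    SimulationConfig,
    StageParams,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_region():
    return GenomicInterval("chr1", 1000, 2000, "ME")


def make_read(read_id, positions, calls, chrom="chr1"):
    """calls given as a string over M/U/. for readability."""
    symbol = {"M": 1, "U": 0, ".": -1}
    return ReadCalls(
        read_id=read_id,
        chrom=chrom,
        positions=np.asarray(positions),
        calls=np.asarray([symbol[c] for c in calls], dtype=np.int8),
    )


@pytest.fixture
def cohort_config():
    """Small cohort with two planted ME regions; fast enough for unit tests."""
    return SimulationConfig(
        chrom_sizes={"chr1": 60_000},
        cpg_spacing_mean=80.0,
        n_individuals=2,
        tissues=("T1", "T2"),
        depth_mean=30.0,
        planted_me_regions=[
            (GenomicInterval("chr1", 10_000, 11_500, "ME"), [0.1, 0.85]),
            (GenomicInterval("chr1", 40_000, 41_500, "ME"), None),
        ],
        snp_density=1e-5,
        seed=11,
    )


@pytest.fixture
def cohort(cohort_config):
    return simulate_cohort(cohort_config)


@pytest.fixture
def stage_config():
    return SimulationConfig(
        chrom_sizes={"chr1": 150_000},
        cpg_spacing_mean=100.0,
        depth_mean=60.0,
        planted_me_regions=[
            (GenomicInterval("chr1", 20_000, 24_000, "ME"), None),
            (GenomicInterval("chr1", 90_000, 94_000, "ME"), None),
        ],
        stage_trajectory={
            "oocyte": StageParams(0.35, 0.2, 0.0),
            "liver": StageParams(0.80, 0.5, 0.5),
        },
        seed=5,
    )


@pytest.fixture
def read_model():
    return ReadModel(n_cpgs_mean=6.0, p_homog=0.5, missing_rate=0.05)
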