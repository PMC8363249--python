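"""Shared fixtures: benchmark records and the reduced-grid search result.

The heavy end-to-end artifacts are session-scoped so the extraction
benchmark, the optimizer checks and the acceptance suite share one run.
Problem sizes are scaled study conditions: 250 Hz, 60–120 s records.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from fecgkit import (
    EEMDConfig,
    FIRSpec,
    PipelineConfig,
    RLSConfig,
    SyntheticConfig,
    generate_record,
    grid_search,
    reduced_space,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# prefilter for the 250 Hz scaled records (study band 3-150 Hz needs fs >= 300)
FIR_250 = FIRSpec(low=3.0, high=100.0, order=500)

BENCH_SYNTH = SyntheticConfig(
    fs=250.0, duration=60.0, seed=1, mr_fr_target=2.0, noise_sd=0.007
)


def base_pipeline(**kw) -> PipelineConfig:
    defaults = dict(
        channels=(0, 1, 2, 3),
        fir=FIR_250,
        rls=RLSConfig(M=16),
        eemd=EEMDConfig(N=10, N_std=0.1, seed=0),
        imfs=frozenset({1, 2, 3}),
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def bench_record():
    """High-quality 60 s benchmark record (mR:fR 2, low noise)."""
    return generate_record(BENCH_SYNTH)


@pytest.fixture(scope="session")
def bench_search(bench_record):
    """Reduced-grid hyperparameter search on the benchmark record."""
    return grid_search(
        bench_record.recording,
        bench_record.fetal_R,
        reduced_space(),
        base=base_pipeline(),
    )


@pytest.fixture(scope="session")
def st_record():
    """Longer (120 s) high-quality record for blockwise ST analysis."""
    return generate_record(dataclasses.replace(BENCH_SYNTH, duration=120.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
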