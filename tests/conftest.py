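import numpy as np
import pandas as pd
import pytest

from cnvdose.simulate import CnvLocus, CohortConfig, make_probe_map, simulate_cohort


@pytest.fixture(scope="session")
def probe_map():
    return make_probe_map(200, seed=2)


@pytest.fixture(scope="session")
def deletion_locus(probe_map):
    return CnvLocus(
        "1",
        int(probe_map["pos"].iloc[80]),
        int(probe_map["pos"].iloc[99]),
        "deletion",
        0.3,
        name="del20",
    )


@pytest.fixture(scope="session")
def clean_cohort(probe_map, deletion_locus):
    """Low-noise cohort without GC/wave artefacts: easy calling ground."""
    cfg = CohortConfig(
        n_samples=80,
        probe_map=probe_map,
        loci=[deletion_locus],
        lrr_sd=0.1,
        baf_sd=0.03,
        gc_slope=0.0,
        wave_amplitude=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort(probe_map, deletion_locus):
    """Cohort with GC slope and genomic wave, as real arrays show."""
    cfg = CohortConfig(
        n_samples=60,
        probe_map=probe_map,
        loci=[deletion_locus],
        lrr_sd=0.15,
        baf_sd=0.04,
        gc_slope=0.5,
        wave_amplitude=0.1,
        wave_period=1_500_000.0,
        seed=13,
    )
    return simulate_cohort(cfg)
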