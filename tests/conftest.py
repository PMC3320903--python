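"""Shared fixtures.

The expensive Monte-Carlo summaries (null rejection rates, transform
powers, the frequency-by-size power crossing, the calling-threshold
pattern) are session-scoped so that every test asserting on them shares
one computation.  Within a fixture the competing methods analyse the
same per-replicate datasets (common random numbers), which is what makes
paired ordering assertions sharp.  Replicate and permutation counts are
the package's desk-scale test sizes (see docs/methods.md); the
acceptance script runs the same quantities at full replication.
"""

import numpy as np
import pytest

from cnvassoc.power_study import analysis_seed, make_replicate, run_replicate
from cnvassoc.simulate import NoiseModel, SimulationConfig

# permutations per CBS test inside Monte-Carlo fixtures; B = 100 is the
# smallest count at which a 0.01-level split is attainable (p_min = 1/101)
TEST_NPERM = 100
ALPHA = 0.05


def outcomes_block(base_seed, design, q, length, snr, reps, methods):
    """Per-replicate rejection outcomes for several methods on shared data.

    methods: {name: (pipeline, setting)}.  Returns {name: bool array}.
    """
    cfg = SimulationConfig(snr=snr)
    noise = NoiseModel()
    out = {name: np.zeros(reps, dtype=bool) for name in methods}
    for rep in range(reps):
        data = make_replicate(base_seed, design, q, length, rep, cfg, noise)
        for name, (method, setting) in methods.items():
            seed = analysis_seed(base_seed, design, q, length, rep,
                                 method, setting)
            out[name][rep] = run_replicate(data, method, setting, ALPHA,
                                           TEST_NPERM, seed)
    return out


@pytest.fixture(scope="session")
def null_outcomes():
    """Type-I outcomes: {design: {method: bool array}} over 500 null
    (snr = 0) replicates per design, nominal level 0.05."""
    methods = {"marker": ("marker", {"transform": "probit"}),
               "cnv": ("cnv", {"alpha_call": 0.01})}
    return {
        design: outcomes_block(101, design, 0.2, 30, 0.0, 500, methods)
        for design in ("cohort", "case_control")
    }


@pytest.fixture(scope="session")
def transform_outcomes():
    """Detection outcomes for the four marker-level analyses (probit /
    none / -log10 / no pooling) on 1000 shared cohort datasets, 30-marker
    CNV at 20% frequency, snr 0.8."""
    methods = {
        "probit": ("marker", {"transform": "probit"}),
        "none": ("marker", {"transform": "none"}),
        "neglog10": ("marker", {"transform": "neglog10"}),
        "nopool": ("marker_nopool", {}),
    }
    return outcomes_block(202, "cohort", 0.2, 30, 0.8, 1000, methods)


@pytest.fixture(scope="session")
def crossing_outcomes():
    """Outcomes for the two power-crossing scenarios: small/common CNV
    (10 markers, q = 20%, case-control) and large/rare CNV (50 markers,
    q = 5%, cohort), marker- vs CNV-level, 150 shared datasets each."""
    methods = {"marker": ("marker", {"transform": "probit"}),
               "cnv": ("cnv", {"alpha_call": 0.01})}
    return {
        "small_common": outcomes_block(303, "case_control", 0.2, 10, 0.8,
                                       150, methods),
        "large_rare": outcomes_block(303, "cohort", 0.05, 50, 0.8,
                                     150, methods),
    }


@pytest.fixture(scope="session")
def threshold_outcomes():
    """CNV-level outcomes at calling thresholds 0.01 and 0.1 for a rare
    (q = 5%, 150 datasets) and a common (q = 20%, 80 datasets) 30-marker
    CNV, cohort design; datasets shared across thresholds."""
    methods = {0.01: ("cnv", {"alpha_call": 0.01}),
               0.1: ("cnv", {"alpha_call": 0.1})}
    return {
        "rare": outcomes_block(404, "cohort", 0.05, 30, 0.8, 150, methods),
        "common": outcomes_block(404, "cohort", 0.2, 30, 0.8, 80, methods),
    }
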