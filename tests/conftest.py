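"""Shared fixtures: the demo genome and the session-scoped simulated experiments.

The three expensive simulations (timing course, fully-labeled control,
licensing-bypass rereplication) are each run once per session at the packaged
study scale — two 500 kb chromosomes, 20 origins, 200 cells, 3 replicates —
and shared by the unit and acceptance tests that read them.
"""

from __future__ import annotations

import numpy as np
import pytest

from rerepseq import pipeline, scenarios
from rerepseq.rerep_sim import simulate_sample

SEED = 20260921


@pytest.fixture(scope="session")
def genome():
    return scenarios.demo_genome()


@pytest.fixture(scope="session")
def origins(genome):
    return scenarios.demo_origins(genome)


@pytest.fixture(scope="session")
def digest_params():
    return scenarios.default_digest_params(SEED)


@pytest.fixture(scope="session")
def timecourse(genome, origins, digest_params):
    """Timing-course experiment: pre-label, second S sampled at 0/12/18/end min."""
    schedules = {
        "T0": scenarios.timing_course_schedule(0.0),
        "T12": scenarios.timing_course_schedule(12.0),
        "T18": scenarios.timing_course_schedule(18.0),
        "Tend": scenarios.timing_course_schedule("complete"),
    }
    raw = pipeline.simulate_timecourse(
        genome, origins, schedules, n_replicates=3, n_cells=200,
        params=digest_params, seed=SEED,
    )
    result = pipeline.process_samples(raw, genome, bin_width=100,
                                      smooth_window=10_000, t0="T0")
    return raw, result


@pytest.fixture(scope="session")
def control_3cc(genome, origins, digest_params, timecourse):
    """Fully-labeled three-cycle control processed with the timing-course T0."""
    raw_tc, _ = timecourse
    raw = {("T0", r): raw_tc[("T0", r)] for r in range(3)}
    for r in range(3):
        raw[("cc3", r)] = simulate_sample(
            genome, origins, scenarios.multi_cycle_schedule(3), 200,
            digest_params, rng_seed=SEED + 1000 + r, sample_id=f"cc3_rep{r + 1}",
        )
    return pipeline.process_samples(raw, genome, bin_width=100,
                                    smooth_window=10_000, t0="T0")


@pytest.fixture(scope="session")
def rerep_domains(genome):
    return scenarios.demo_rerep_domains(genome)


@pytest.fixture(scope="session")
def rerep_result(genome, origins, digest_params, timecourse, rerep_domains):
    """Licensing-bypass rereplication processed with the timing-course T0."""
    raw_tc, _ = timecourse
    raw = {("T0", r): raw_tc[("T0", r)] for r in range(3)}
    schedule = scenarios.rerep_bypass_schedule(rerep_domains)
    for r in range(3):
        raw[("gal", r)] = simulate_sample(
            genome, origins, schedule, 200, digest_params,
            rng_seed=SEED + 2000 + r, sample_id=f"gal_rep{r + 1}",
        )
    return pipeline.process_samples(raw, genome, bin_width=100,
                                    smooth_window=10_000, t0="T0")


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
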