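"""Shared fixtures: a seeded synthetic assembly with coverage, reused
across test modules (generation is deterministic, so session scope is safe).
"""

import numpy as np
import pandas as pd
import pytest

import sexscaff as ss

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_genome_truth():
    spec = ss.GenomeSpec(seed=DEFAULT_SEED)
    return ss.generate_genome(spec)


@pytest.fixture(scope="session")
def default_truth(default_genome_truth):
    return default_genome_truth[1]


@pytest.fixture(scope="session")
def default_coverage(default_truth):
    return ss.simulate_coverage(default_truth)


@pytest.fixture(scope="session")
def default_profiles(default_coverage):
    table = default_coverage
    return {
        s: ss.normalize_profile(ss.compute_raw_coverage(table, s))
        for s in table.sample_ids
    }


def make_table(lengths, counts, samples=None):
    """Small hand-built coverage table; counts = {sample: [..]}."""
    ids = [f"s{i}" for i in range(len(lengths))]
    if samples is None:
        samples = {
            sid: ss.SampleInfo(sid, "U", 100) for sid in counts
        }
    return ss.CoverageTable(
        lengths=pd.Series(lengths, index=ids, dtype=float),
        values=pd.DataFrame(counts, index=ids),
        samples=samples,
    )
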