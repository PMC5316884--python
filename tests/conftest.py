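import numpy as np
import pandas as pd
import pytest

from meningomics.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """One shared 8v8 synthetic cohort (seed 7) for integration-style tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    config = CohortConfig(n_atypical=8, n_benign=8, seed=7)
    paths, truth = generate_cohort(config, outdir)
    return config, paths, truth, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def two_group_matrix(n_features, n_per_group, effect_idx=(), effect=0.0, sd=1.0, seed=0, baseline=8.0):
    """Features x samples matrix with a planted two-group shift; helper used
    by several differential-test suites."""
    rng = np.random.default_rng(seed)
    samples = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    grades = {s: ("atypical" if s.startswith("A") else "benign") for s in samples}
    values = baseline + rng.normal(0, sd, size=(n_features, 2 * n_per_group))
    for i in effect_idx:
        values[i, :n_per_group] += effect
    matrix = pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)], columns=samples)
    return matrix, grades
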