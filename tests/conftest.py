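import numpy as np
import pytest

from djpls.body_model.inertia import load_segment_model
from djpls.pipeline_cli import RunConfig, analyze_trial
from djpls.synthetic_data import generate_trial


@pytest.fixture(scope="session")
def segment_model():
    return load_segment_model()


@pytest.fixture(scope="session")
def noiseless_trial():
    """One noise-free synthetic drop jump plus its ground truth."""
    return generate_trial(seed=7)


@pytest.fixture(scope="session")
def noiseless_features(noiseless_trial):
    """Analyzer output on the noiseless trial, forces unfiltered so event
    timing can be compared to truth at sample resolution."""
    recording, _ = noiseless_trial
    return analyze_trial(recording, RunConfig(filter_forces=False))


@pytest.fixture(scope="session")
def small_cohort_table():
    """A 12-participant synthetic feature table (for statistics smoke tests)."""
    from djpls.pipeline_cli import build_feature_table
    from djpls.synthetic_data import sample_population

    config = RunConfig()
    population = sample_population(12, seed=42)
    per_participant = {}
    for i, trials in enumerate(population):
        rows = [
            analyze_trial(
                generate_trial(p, a, seed=s, with_kinetics_truth=False)[0], config
            )
            for p, a, s in trials
        ]
        per_participant[f"P{i:03d}"] = rows
    return build_feature_table(per_participant, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
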