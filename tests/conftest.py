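import pandas as pd
import pytest

from kneeqs.simulate import SyntheticConfig, generate_dataset
from kneeqs.stiffness import summarize_dataset


@pytest.fixture(scope="session")
def noiseless_run():
    """Default-design cohort with zero moment noise: exact piecewise-linear loops."""
    cfg = SyntheticConfig(noise_frac=0.0, seed=20130322)
    dataset, truth = generate_dataset(cfg)
    summaries, exclusions = summarize_dataset(dataset)
    assert not exclusions
    return cfg, dataset, truth, summaries


@pytest.fixture(scope="session")
def default_run():
    """Default-design cohort with the standard 3% moment noise."""
    cfg = SyntheticConfig(seed=20130322)
    dataset, truth = generate_dataset(cfg)
    summaries, exclusions = summarize_dataset(dataset)
    assert not exclusions
    return cfg, dataset, truth, summaries


@pytest.fixture(scope="session")
def default_summary_frame(default_run):
    _, _, _, summaries = default_run
    return pd.DataFrame([vars(s) for s in summaries])
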