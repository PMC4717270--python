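import numpy as np
import pandas as pd
import pytest

from proturn import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """Two groups, small and noiseless-ish study for fast integration tests."""
    return simulate.StudyDesign(
        groups=("young_EDL", "old_EDL"),
        n_animals_per_group=2,
        noise_cv=0.05,
        missing_rate=0.0,
        seed=7,
    )


@pytest.fixture
def noiseless_design():
    return simulate.StudyDesign(
        groups=("young_EDL", "old_EDL"),
        n_animals_per_group=1,
        noise_cv=0.0,
        missing_rate=0.0,
        seed=7,
    )


def make_percent_new(true_half_life, times=(3, 7, 12, 17), peptide="pep1"):
    """Exact noiseless percent-new observations for one peptide."""
    k = np.log(2.0) / true_half_life
    return pd.DataFrame(
        {
            "peptide_id": peptide,
            "time_days": list(times),
            "percent_new": [100.0 * (1.0 - np.exp(-k * t)) for t in times],
        }
    )
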