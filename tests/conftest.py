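import numpy as np
import pandas as pd
import pytest

from volatilome import PeakTable
from volatilome import synthdata as sd


@pytest.fixture(scope="session")
def default_dataset():
    """Default study design, seed 1: 13 species x 5 strains x 3 reps + 6 blanks,
    403 peaks."""
    spec = sd.SyntheticSpec(seed=1)
    table, meta, truth = sd.generate_dataset(spec)
    return spec, table, meta, truth


@pytest.fixture(scope="session")
def small_spec():
    """A reduced design for fast unit tests."""
    return sd.SyntheticSpec(
        n_species=4, strains_per_species=3, tech_reps=3,
        n_signal_peaks=40, n_noise_peaks=30, n_blanks=4,
        n_general_peaks=4, n_specific_peaks_per_species=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return (small_spec,) + sd.generate_dataset(small_spec)


def random_table(rng, n_samples=10, n_peaks=5, prefix="s"):
    mz = np.sort(rng.uniform(28, 300, n_peaks))
    cols = [f"ms{m:.4f}" for m in mz]
    data = pd.DataFrame(np.abs(rng.normal(5, 2, (n_samples, n_peaks))),
                        index=[f"{prefix}{i}" for i in range(n_samples)], columns=cols)
    return PeakTable(data, units="ppbV")
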