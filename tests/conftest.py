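import numpy as np
import pandas as pd
import pytest

from poolstruct import simulate


@pytest.fixture(scope="session")
def group_model():
    return simulate.generate_group_frequencies(300, 3, fst=0.2, seed=11)


@pytest.fixture(scope="session")
def truth(group_model):
    return simulate.generate_landraces(group_model, 15, frac_admixed=0.2,
                                       drift=0.01, n_plants=15, seed=12)


@pytest.fixture(scope="session")
def fluo_cal(truth):
    return simulate.generate_fluorescence(truth, seed=13,
                                          n_calibration_snps=300)


@pytest.fixture(scope="session")
def called_panel(fluo_cal):
    from poolstruct import genotyping

    fluo, cal = fluo_cal
    return genotyping.call_frequencies(fluo, cal)


@pytest.fixture()
def random_panel():
    """Small dense random panel for brute-force oracle comparisons."""
    rng = np.random.default_rng(77)
    freq = rng.uniform(0, 1, size=(10, 50))
    from poolstruct.genotyping import PanelFrequencies

    return PanelFrequencies(pd.DataFrame(
        freq, index=[f"LR{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(50)]))


@pytest.fixture(scope="session")
def trial_records(truth):
    design = simulate.default_trial_design(truth, seed=14)
    return simulate.generate_trials(truth, design, seed=14)
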