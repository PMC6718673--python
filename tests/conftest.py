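import numpy as np
import pytest

import twinsig as ts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_cfg():
    """Single-neuron, zero-noise trace config with known amplitudes."""
    return ts.TraceSimConfig(
        noise_sd=0.0, neuron_fraction=1.0, n_cells=3,
        stimulus_amplitudes={"GABA": 0.5, "GluGlyNoMg": 0.6, "KCl": 1.0,
                             "ionomycin": 2.0},
    )


@pytest.fixture
def small_design():
    return ts.CohortDesign(n_pairs=2, cells_per_subject=8, true_pair_effect=0.3,
                           between_pair_sd=0.05, within_subject_cell_sd=0.1)
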