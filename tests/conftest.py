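import numpy as np
import pytest

import fncpipe as f


@pytest.fixture(scope="session")
def reduced_study():
    """A 12+12-subject reduced synthetic study shared across tests."""
    cfg = f.SynthConfig.reduced(n_young=12, n_old=12, seed=7)
    return f.simulate_study(cfg)


@pytest.fixture(scope="session")
def fitted_model(reduced_study):
    """Group ICA fitted to the reduced study, with subject components."""
    from fncpipe.pipeline import fit_ica_stage, study_from_memory

    data = study_from_memory(reduced_study)
    model, comps = fit_ica_stage(
        data, n_ic=6, run_pcs=20, n_reps=5, seed=3
    )
    return data, model, comps


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
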