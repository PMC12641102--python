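import numpy as np
import pytest

from clavibmd import phantom, training
from clavibmd.network import NetworkSpec


@pytest.fixture(scope="session")
def tiny_params():
    """A small, fast cohort configuration used across unit tests."""
    return phantom.CohortParams(n_cases=24, image_size=32, seed=5)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return {s.case_id: s for s in phantom.generate_cohort(tiny_params)}


@pytest.fixture(scope="session")
def phantom_study():
    """The scaled-down 5-fold study of both models on a n=400 cohort.

    Expensive (minutes); computed once per session and shared by the
    end-to-end recovery and explainability tests.
    """
    params = phantom.CohortParams(n_cases=400, image_size=64, seed=7)
    cohort = {s.case_id: s for s in phantom.generate_cohort(params)}
    cfg = training.TrainConfig(learning_rate=2e-3, batch_size=16,
                               epochs_multi=8, epochs_single=4, seed=1)
    multi = NetworkSpec(base_filters=8, convs_per_stage=2, input_size=64,
                        mode="multi_task", seed=1)
    single = NetworkSpec(base_filters=8, convs_per_stage=2, input_size=64,
                         mode="single_task", seed=1)
    preds_multi, hists_multi = training.run_crossval(multi, cfg, cohort, k=5)
    preds_single, hists_single = training.run_crossval(single, cfg, cohort, k=5)
    return {"cohort": cohort, "preds_multi": preds_multi,
            "preds_single": preds_single, "hists_multi": hists_multi,
            "hists_single": hists_single}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
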