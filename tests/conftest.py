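import numpy as np
import pytest

import somnowave as sw
from somnowave.features import build_feature_matrix, split_features
from somnowave.stages import STAGES


@pytest.fixture(scope="session")
def maxflat_bank():
    """Length-7 maximal-regularity halfband with its minimal PR partner."""
    h0 = sw.design_halfband_analysis(L=7, alpha=1.0, gamma=0.0, R=2)
    f0 = sw.design_synthesis_lowpass(h0, M=9, V=2)
    return sw.make_filter_bank(h0, f0)


@pytest.fixture(scope="session")
def default_bank():
    return sw.design_filter_bank()


@pytest.fixture(scope="session")
def stage_cohort():
    """50 epochs per stage at 256 Hz / 4 s -- small but spectrally faithful."""
    spec = sw.CohortSpec(
        (("synthetic", {s: 50 for s in STAGES}),), fs=256.0, epoch_s=4.0, seed=11
    )
    return sw.generate_cohort(spec)


@pytest.fixture(scope="session")
def stage_features(stage_cohort, default_bank):
    return build_feature_matrix(stage_cohort, default_bank)


@pytest.fixture(scope="session")
def stage_Xy(stage_features):
    X, y = split_features(stage_features)
    return X.to_numpy(), list(y)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
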