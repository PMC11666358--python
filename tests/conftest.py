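import numpy as np
import pytest

from ricenni import (
    build_feature_table,
    default_config,
    run_nni_pipeline,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic campaign (seed 42), shared across the session."""
    return simulate_trial(default_config(seed=42))


@pytest.fixture(scope="session")
def default_nni(default_dataset):
    return run_nni_pipeline(default_dataset.plots)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return build_feature_table(default_dataset.spad)


@pytest.fixture(scope="session")
def modelling_frame(default_dataset, default_nni, default_features):
    """Features + targets aligned on observations with a defined NNI."""
    table = default_nni.plots.set_index("obs_id")
    usable = default_features.index.intersection(table.index[table["nni"].notna()])
    feats = default_features.loc[usable]
    targets = {"LNC": table.loc[usable, "lnc"], "NNI": table.loc[usable, "nni"]}
    return feats, targets


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
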