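import numpy as np
import pandas as pd
import pytest

import larvopt as lv
from larvopt.encoding import aggregate_replicates


@pytest.fixture(scope="session")
def noise_free_means() -> pd.DataFrame:
    """Condition means of a noise-free synthetic dataset (interpolation regime)."""
    df = lv.generate_dataset(lv.GenerationConfig(seed=42, noise_sd_fraction=0.0))
    return aggregate_replicates(df)


@pytest.fixture(scope="session")
def noisy_mean_table() -> pd.DataFrame:
    """Condition means under the default 3% replicate noise."""
    df = lv.generate_dataset(lv.GenerationConfig(seed=0))
    return aggregate_replicates(df)


@pytest.fixture(scope="session")
def identity_models(noise_free_means) -> dict[str, lv.MLPSurrogate]:
    """Fast exactly-interpolating surrogates (identity activations), one per group."""
    models = {}
    for gi, group in enumerate(lv.GROUPS):
        models[group], _ = lv.train(
            noise_free_means, group, hidden=10, activations=("identity", "identity"),
            seed=100 + gi,
        )
    return models


@pytest.fixture(scope="session")
def tanh_models(noisy_mean_table) -> dict[str, lv.MLPSurrogate]:
    """Nonlinear surrogates trained on noisy means (generic-weights case)."""
    models = {}
    for gi, group in enumerate(lv.GROUPS):
        models[group], _ = lv.train(
            noisy_mean_table, group, hidden=10, activations=("tanh", "identity"),
            seed=200 + gi,
        )
    return models


def toy_model(w1, b1, w2, b2, hidden_act="identity", output_act="identity",
              in_names=None, out_names=None):
    """Hand-built surrogate with explicit min-max ranges [0, 1] (no-op scaling)."""
    w1 = np.atleast_2d(np.asarray(w1, dtype=float))
    w2 = np.atleast_2d(np.asarray(w2, dtype=float))
    m, q = w1.shape[1], w2.shape[0]
    in_names = in_names or [f"x{i}" for i in range(m)]
    out_names = out_names or [f"y{j}" for j in range(q)]
    return lv.MLPSurrogate(
        group="proximate",
        output_names=list(out_names),
        input_to_hidden_weights=w1,
        hidden_biases=np.asarray(b1, dtype=float),
        hidden_to_output_weights=w2,
        output_biases=np.asarray(b2, dtype=float),
        hidden_activation=hidden_act,
        output_activation=output_act,
        input_scaling=lv.MinMaxScaler(names=in_names, mins=np.zeros(m), maxs=np.ones(m)),
        output_scaling=lv.MinMaxScaler(names=out_names, mins=np.zeros(q), maxs=np.ones(q)),
    )
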