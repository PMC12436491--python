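import numpy as np
import pandas as pd
import pytest

from fitbmi import default_config, simulate_cohort
from fitbmi.encoder import _fit_count_bins, init_encoder, loss_and_grads
from fitbmi.losses import LossWeights
from fitbmi.preprocess import SequenceBatch


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-record synthetic cohort with the default planted structure."""
    return simulate_cohort(default_config(n=600, seed=7)).df


@pytest.fixture()
def tiny_batch():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(12, 4))
    y = rng.integers(0, 4, 12)
    return SequenceBatch(x=x, labels=y, record_index=np.arange(12), full=x)


@pytest.fixture()
def hand_cohort_df():
    """Six hand-entered records covering all four categories."""
    height = np.array([175.0, 172.0, 180.0, 168.0, 176.0, 170.0])
    bmi = np.array([17.2, 21.0, 23.5, 26.0, 31.5, 19.0])
    return pd.DataFrame({
        "id": np.arange(1, 7),
        "run_3000m_s": [820.0, 760.0, 905.0, 850.0, 990.0, 800.0],
        "pullups": [12, 15, 6, 4, 1, 10],
        "situps": [44, 50, 38, 35, 25, 41],
        "shuttle_60m_s": [9.8, 9.5, 10.6, 10.9, 12.0, 10.0],
        "height_cm": height,
        "weight_kg": bmi * (height / 100.0) ** 2,
        "bmi": bmi,
        "bmi_category": ["A", "B", "B", "C", "D", "B"],
    })


def finite_difference_gradcheck(params, batch, loss_weights, step=1e-5):
    """Max relative error between backprop and central finite differences."""
    _, grads = loss_and_grads(params, batch, loss_weights)
    worst = 0.0
    for name, tensor in params.tensors.items():
        flat = tensor.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            up, _ = loss_and_grads(params, batch, loss_weights,
                                   compute_grads=False)
            flat[i] = orig - step
            dn, _ = loss_and_grads(params, batch, loss_weights,
                                   compute_grads=False)
            flat[i] = orig
            fd = (up["total"] - dn["total"]) / (2 * step)
            g = grads[name].reshape(-1)[i]
            worst = max(worst, abs(fd - g) / max(1e-8, abs(fd) + abs(g)))
    return worst


@pytest.fixture()
def tiny_encoder(tiny_batch):
    from fitbmi.encoder import EncoderConfig

    cfg = EncoderConfig(kernel_widths=(2, 3), channels_per_kernel=3,
                        attention_dim=4, seed=1)
    params = init_encoder(cfg)
    params.count_bin_edges = _fit_count_bins(cfg, tiny_batch.full)
    return params


@pytest.fixture()
def balanced_loss_weights():
    return LossWeights(class_weights=np.array([1.2, 0.8, 1.0, 2.0]))
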