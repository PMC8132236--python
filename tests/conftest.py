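import numpy as np
import pytest

import jointfair as jf


def random_instance(seed, K=2, p=6, n=(60, 40), prevalence_beta_scale=1.0):
    """Small random grouped logistic dataset with both classes per group."""
    rng = np.random.default_rng(seed)
    beta = prevalence_beta_scale * rng.standard_normal(p)
    Xs, ys = [], []
    for nk in n[:K]:
        while True:
            Xk = rng.standard_normal((nk, p))
            pk = 1.0 / (1.0 + np.exp(-(Xk @ beta)))
            yk = (rng.random(nk) < pk).astype(float)
            if 0 < yk.sum() < nk:
                break
        Xs.append(Xk)
        ys.append(yk)
    labels = [f"g{k}" for k in range(K)]
    return jf.GroupedDataset(X=Xs, y=ys, labels=labels)


@pytest.fixture
def small_data():
    """Hand-sized two-group dataset, deterministic."""
    return random_instance(0)


@pytest.fixture
def three_group_data():
    return random_instance(1, K=3, n=(40, 30, 25))
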