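import numpy as np
import pytest

import splitfedlab as sfl


def tiny_spec(n_classes: int = 3, image_size: int = 8) -> sfl.SplitModelSpec:
    """A miniature split CNN for gradient-oracle tests."""
    return sfl.SplitModelSpec(
        layers=[("conv", 2, 3, 1), ("relu",), ("maxpool", 2),
                ("flatten",), ("dense", 5), ("relu",), ("dense", n_classes)],
        cut_index=3, n_classes=n_classes, image_size=image_size)


@pytest.fixture(scope="session")
def tiny_model():
    return sfl.build_split_model(tiny_spec(), seed=42)


@pytest.fixture(scope="session")
def synth_small():
    """Small preprocessed synthetic set for fast protocol tests."""
    data = sfl.generate_synthetic_images(30, 4, 16, seed=3)
    return sfl.preprocess(data)


@pytest.fixture(scope="session")
def trained_splitfed():
    """The reference experiment: 4-class synthetic set (200 per class,
    32x32, seed 0), SplitFed with 2 clients, Adam/AMSGrad lr 1e-3 batch 64,
    trained until held-out accuracy >= 0.90. Shared across the privacy and
    utility tests."""
    data = sfl.generate_synthetic_images(200, 4, 32, seed=0)
    pre = sfl.preprocess(data)
    train_set, test_set = sfl.train_test_split_set(pre, 0.2, seed=0)
    plan = sfl.partition(train_set, 2, seed=0)
    cfg = sfl.TrainConfig(n_clients=2, epochs=15, batch_size=64, lr=1e-3,
                          optimizer="adam", amsgrad=True, seed=0,
                          target_accuracy=0.90)
    state, history = sfl.train(train_set, plan, cfg, eval_data=test_set)
    return {"state": state, "history": history, "train": train_set,
            "test": test_set, "cfg": cfg, "data": data}


def finite_diff_grads(fn, arrays, eps: float = 1e-6):
    """Central finite differences of a scalar function of the given arrays."""
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            hi = fn()
            arr[idx] = orig - eps
            lo = fn()
            arr[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
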