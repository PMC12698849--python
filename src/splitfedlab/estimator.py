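"""scikit-learn compatible front end for split-federated training.

``SplitFedClassifier`` wraps the protocol functions so the simulator drops
into sklearn pipelines and model selection: ``fit(X, y)`` partitions the
samples across simulated clients and runs the SplitFed loop; ``predict``
runs the aggregated global model.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import LabeledImageSet, partition, preprocess
from .dp import NoiseSpec
from .model import predict as model_predict
from .nn import softmax
from .protocol import TrainConfig, train


class SplitFedClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class image classifier trained with split federated learning.

    Parameters
    ----------
    n_clients : simulated healthcare institutions holding disjoint shards.
    epochs, batch_size, lr, optimizer, amsgrad : training schedule; the
        default is Adam with AMSGrad, lr 1e-3, batch 64.
    image_size : side length; ``X`` rows are flattened square grayscale
        images (or pass ``X`` with shape (n, H, W)).
    noise : optional :class:`NoiseSpec` enabling the DP defense during
        training.
    target_accuracy : stop early once this held-out accuracy is reached
        (requires ``eval_set`` in ``fit``).
    random_state : seed for initialization, shuffling and noise.
    """

    def __init__(self, n_clients: int = 2, epochs: int = 15,
                 batch_size: int = 64, lr: float = 1e-3,
                 optimizer: str = "adam", amsgrad: bool = True,
                 image_size: int = 32, noise: NoiseSpec | None = None,
                 aggregate_every: int = 1, target_accuracy: float | None = None,
                 random_state: int = 0):
        self.n_clients = n_clients
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.optimizer = optimizer
        self.amsgrad = amsgrad
        self.image_size = image_size
        self.noise = noise
        self.aggregate_every = aggregate_every
        self.target_accuracy = target_accuracy
        self.random_state = random_state

    def _as_image_set(self, X, y=None) -> LabeledImageSet:
        X = np.asarray(X, dtype=np.float64)
        s = self.image_size
        if X.ndim == 2:
            if X.shape[1] != s * s:
                raise ValueError(
                    f"expected {s * s} features for {s}x{s} images, got {X.shape[1]}")
            X = X.reshape(-1, s, s)
        elif X.ndim != 3:
            raise ValueError("X must be (n, H*W) or (n, H, W)")
        labels = np.zeros(len(X), dtype=np.int64) if y is None else \
            np.asarray(y, dtype=np.int64)
        names = tuple(str(c) for c in (self.classes_ if hasattr(self, "classes_")
                                       else np.unique(labels)))
        ds = LabeledImageSet(X, labels, names if names else ("0",),
                             value_range=(0.0, 255.0))
        return preprocess(ds)

    def fit(self, X, y, eval_set=None):
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        X = np.asarray(X, dtype=np.float64)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else \
            X.shape[1] * X.shape[2]
        data = self._as_image_set(X, y_enc)
        cfg = TrainConfig(n_clients=self.n_clients, epochs=self.epochs,
                          batch_size=self.batch_size, lr=self.lr,
                          optimizer=self.optimizer, amsgrad=self.amsgrad,
                          seed=self.random_state, noise=self.noise,
                          aggregate_every=self.aggregate_every,
                          target_accuracy=self.target_accuracy,
                          n_classes=len(self.classes_),
                          image_size=self.image_size)
        eval_data = None
        if eval_set is not None:
            Xe, ye = eval_set
            eval_data = self._as_image_set(np.asarray(Xe, dtype=np.float64),
                                           np.searchsorted(self.classes_,
                                                           np.asarray(ye)))
        plan = partition(data, self.n_clients, seed=self.random_state)
        self.state_, self.history_ = train(data, plan, cfg, eval_data=eval_data)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "state_")
        data = self._as_image_set(X)
        model = self.state_.model()
        x = data.images[:, None, :, :]
        scores = []
        for i in range(0, len(x), 256):
            scores.append(model.server.forward(model.client.forward(x[i:i + 256])))
        return np.concatenate(scores)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        check_is_fitted(self, "state_")
        data = self._as_image_set(X)
        return self.classes_[model_predict(self.state_.model(), data.images)]
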