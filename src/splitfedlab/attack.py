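"""Gradient-matching label inference attack.

The adversary observes, for a single sample, the gradient of the training
loss with respect to the parameters of one model part (by default the
client part — the quantity a curious aggregation server sees in every
client update). Holding a clone of the model, it enumerates every candidate
label, recomputes the same gradient under each candidate, and infers the
label whose clone gradient has the smallest mean squared error against the
observation. With an exact clone and a noiseless observation the MSE at the
true label is exactly zero, so the attack is perfect whenever distinct
labels produce distinct gradients.

Noise added to the transmitted gradients (the differential-privacy defense)
is what breaks this matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import LabeledImageSet
from .dp import NoiseSpec, sample_noise
from .model import SplitModel
from .nn import Sequential, cross_entropy


@dataclass
class ObservedGradient:
    """Per-sample observation available to the adversary."""

    grad_flat: np.ndarray           # d loss / d (attacked-part parameters), flat
    cut_activation: np.ndarray      # activations at the split for this sample
    part_input: np.ndarray          # input fed to the attacked part
    true_label: int
    sample_index: int = -1


@dataclass
class AttackResult:
    """Inferred labels with per-candidate MSEs and summary accuracy."""

    inferred: np.ndarray
    true_labels: np.ndarray
    mses: np.ndarray                # (n_samples, n_candidates)
    accuracy: float = 0.0
    n_grad_evals: int = 0

    def __post_init__(self) -> None:
        self.inferred = np.asarray(self.inferred, dtype=np.int64)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        if len(self.inferred):
            self.accuracy = float((self.inferred == self.true_labels).mean())

    def to_dict(self) -> dict:
        return {"kind": "attack_result", "accuracy": self.accuracy,
                "inferred": self.inferred.tolist(),
                "true_labels": self.true_labels.tolist(),
                "mses": self.mses.tolist(), "n_grad_evals": self.n_grad_evals}


@dataclass
class AttackConfig:
    n_samples: int = 100
    seed: int = 0
    noise: Optional[NoiseSpec] = None     # transmission noise on observations
    clone: str = "exact"                  # "exact" or "reinit"
    attacked_part: str = "client"         # whose parameter gradients leak
    label_set: Optional[list[int]] = None
    debias: bool = True                   # adversary subtracts the known noise mean

    def to_dict(self) -> dict:
        d = {"n_samples": self.n_samples, "seed": self.seed,
             "clone": self.clone, "attacked_part": self.attacked_part}
        if self.noise is not None:
            d["noise"] = self.noise.to_dict()
        return d


def _parts(model: SplitModel, attacked_part: str) -> tuple[Sequential, Sequential, Sequential]:
    """(pre, attacked, post) so that loss = CE(post(attacked(pre(x))), y)."""
    if attacked_part == "client":
        return Sequential([]), model.client, model.server
    if attacked_part == "server":
        return model.client, model.server, Sequential([])
    raise ValueError("attacked_part must be 'client' or 'server'")


def grad_for_label(attacked: Sequential, post: Sequential, part_input: np.ndarray,
                   label: int) -> np.ndarray:
    """Flat gradient of the single-sample loss w.r.t. the attacked part's
    parameters, for a given (candidate or true) label."""
    attacked.zero_grad()
    post.zero_grad()
    scores = post.forward(attacked.forward(part_input))
    _, dlogits = cross_entropy(scores, np.asarray([label]))
    attacked.backward(post.backward(dlogits))
    grads = attacked.grad_arrays()
    if not grads:
        raise ValueError("attacked part has no parameters")
    return np.concatenate([g.ravel() for g in grads])


def record_observed_gradients(model: SplitModel, samples: LabeledImageSet,
                              attacked_part: str = "client",
                              noise: Optional[NoiseSpec] = None,
                              rng: Optional[np.random.Generator] = None
                              ) -> list[ObservedGradient]:
    """Exact per-sample parameter gradients at the true labels, plus the cut
    activation; when transmission noise is enabled the recorded gradient is
    the noisy one the adversary would see."""
    if len(samples) == 0:
        raise ValueError("no samples to observe")
    if samples.value_range != (-1.0, 1.0):
        from .data import preprocess

        samples = preprocess(samples)
    if noise is not None and rng is None:
        rng = np.random.default_rng(noise.seed)
    pre, attacked, post = _parts(model, attacked_part)
    out = []
    for j in range(len(samples)):
        x = samples.images[j][None, None, :, :]
        part_input = pre.forward(x) if pre.layers else x
        g = grad_for_label(attacked, post, part_input, int(samples.labels[j]))
        if noise is not None:
            g = g + sample_noise(noise, g.shape, rng)
        cut = model.client.forward(x)
        out.append(ObservedGradient(grad_flat=g, cut_activation=cut[0],
                                    part_input=part_input,
                                    true_label=int(samples.labels[j]),
                                    sample_index=j))
    return out


def infer_label(clone_attacked: Sequential, clone_post: Sequential,
                obs: ObservedGradient, label_set) -> tuple[int, np.ndarray]:
    """Enumerate candidate labels; return the argmin-MSE label (lowest index
    on exact ties) and the per-candidate MSE vector."""
    label_set = list(label_set)
    if not label_set:
        raise ValueError("empty candidate label set")
    mses = np.empty(len(label_set))
    for i, z in enumerate(label_set):
        g = grad_for_label(clone_attacked, clone_post, obs.part_input, int(z))
        if g.shape != obs.grad_flat.shape:
            raise ValueError("clone gradient length does not match observation")
        mses[i] = float(np.mean((obs.grad_flat - g) ** 2))
    return int(label_set[int(np.argmin(mses))]), mses


def candidate_gradients(model: SplitModel, samples: LabeledImageSet,
                        label_set, attacked_part: str = "client",
                        clone: str = "exact", seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Clean observed gradients and all candidate clone gradients.

    Returns ``(obs, cand)`` with shapes (n, p) and (n, |labels|, p); the
    noise-free building blocks the sweep reuses across noise settings.
    """
    label_set = list(label_set)
    clone_model = _make_clone(model, clone, seed)
    pre, attacked, post = _parts(clone_model, attacked_part)
    obs_list = record_observed_gradients(model, samples, attacked_part)
    n, p = len(obs_list), obs_list[0].grad_flat.size
    obs = np.empty((n, p))
    cand = np.empty((n, len(label_set), p))
    for j, ob in enumerate(obs_list):
        obs[j] = ob.grad_flat
        for i, z in enumerate(label_set):
            cand[j, i] = grad_for_label(attacked, post, ob.part_input, int(z))
    return obs, cand


def _make_clone(model: SplitModel, clone: str, seed: int) -> SplitModel:
    from .model import build_split_model

    if clone == "exact":
        return model.copy()
    if clone == "reinit":
        return build_split_model(model.spec, seed=seed + 1)
    raise ValueError("clone must be 'exact' or 'reinit'")


def run_attack(model_or_state, test_subset: LabeledImageSet,
               cfg: AttackConfig | None = None) -> AttackResult:
    """Record observed gradients and infer a label for every sample.

    ``model_or_state`` is a :class:`SplitModel` or a protocol
    ``FederatedState``. Deterministic given the model and subset when no
    transmission noise is configured.
    """
    cfg = cfg or AttackConfig()
    model = model_or_state.model() if hasattr(model_or_state, "model") \
        else model_or_state
    if len(test_subset) == 0:
        raise ValueError("empty attack subset")
    n = min(cfg.n_samples, len(test_subset))
    subset = test_subset.subset(np.arange(n))
    label_set = cfg.label_set if cfg.label_set is not None \
        else list(range(model.spec.n_classes))
    rng = np.random.default_rng([cfg.seed, 3])
    observations = record_observed_gradients(
        model, subset, cfg.attacked_part, cfg.noise, rng)
    if cfg.noise is not None and cfg.debias:
        # the mechanism is public: the adversary re-centers the observation
        # by the noise mean (a no-op for mean-free Cauchy at gamma = 0)
        from .dp import noise_center

        center = noise_center(cfg.noise)
        for obs in observations:
            obs.grad_flat = obs.grad_flat - center
    clone_model = _make_clone(model, cfg.clone, cfg.seed)
    _, clone_attacked, clone_post = _parts(clone_model, cfg.attacked_part)
    inferred = np.empty(n, dtype=np.int64)
    mses = np.empty((n, len(label_set)))
    for j, obs in enumerate(observations):
        inferred[j], mses[j] = infer_label(clone_attacked, clone_post, obs,
                                           label_set)
    return AttackResult(inferred=inferred, true_labels=subset.labels,
                        mses=mses, n_grad_evals=n * len(label_set))
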