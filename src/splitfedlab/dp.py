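"""Differential-privacy style noise injection.

Additive noise from four families (Gaussian, Laplace, Cauchy, Exponential)
applied at three points of the split-federated protocol: model parameters
shared upward, transmissions (smashed activations client->server, gradients
server->client), and — in plain-SGD mode — directly inside the update rule.
No formal (epsilon, delta) accounting is performed: there is no sensitivity
or clipping analysis here, only calibrated-noise obfuscation; the scale sigma
is the privacy/utility dial.

The exponential family is one-sided; draws are ``gamma + Exp(mean=sigma)``,
so ``sigma`` is the mean of the shifted draw and ``gamma`` shifts its support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import ParameterVector, SmashedBatch

FAMILIES = ("gaussian", "laplace", "cauchy", "exponential")
TARGETS = ("parameters", "activations", "gradients")


@dataclass
class NoiseSpec:
    """Noise family, location gamma, scale sigma > 0, and injection targets."""

    family: str = "cauchy"
    gamma: float = 0.0
    sigma: float = 1.0
    targets: tuple[str, ...] = ("gradients",)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        self.targets = tuple(self.targets)
        unknown = set(self.targets) - set(TARGETS)
        if unknown:
            raise ValueError(f"unknown noise targets {sorted(unknown)}")
        if not self.targets:
            raise ValueError("targets must be non-empty")

    def to_dict(self) -> dict:
        return {"family": self.family, "gamma": self.gamma, "sigma": self.sigma,
                "targets": list(self.targets), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(family=d["family"], gamma=float(d.get("gamma", 0.0)),
                   sigma=float(d.get("sigma", 1.0)),
                   targets=tuple(d.get("targets", ("gradients",))),
                   seed=d.get("seed"))


@dataclass
class NoisyTransmissionRecord:
    """Original transmission, the noise realization, and their exact sum."""

    original: np.ndarray
    noise: np.ndarray
    noisy: np.ndarray
    metadata: dict = field(default_factory=dict)


def cauchy_pdf(x: np.ndarray | float, gamma: float = 0.0, sigma: float = 1.0):
    """Cauchy density 1 / (pi sigma [1 + ((x - gamma)/sigma)^2])."""
    x = np.asarray(x, dtype=np.float64)
    val = 1.0 / (np.pi * sigma * (1.0 + ((x - gamma) / sigma) ** 2))
    return float(val) if val.ndim == 0 else val


def sample_noise(spec: NoiseSpec, shape, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. draws from the spec's family with location gamma and scale sigma."""
    if spec.family == "gaussian":
        return rng.normal(spec.gamma, spec.sigma, shape)
    if spec.family == "laplace":
        return rng.laplace(spec.gamma, spec.sigma, shape)
    if spec.family == "cauchy":
        return spec.gamma + spec.sigma * rng.standard_cauchy(shape)
    if spec.family == "exponential":
        return spec.gamma + rng.exponential(spec.sigma, shape)
    raise ValueError(f"unknown noise family {spec.family!r}")  # pragma: no cover


def noise_center(spec: NoiseSpec) -> float:
    """The centering constant an adversary who knows the mechanism subtracts
    from a noisy observation: the distribution mean where it exists (gamma for
    Gaussian/Laplace, gamma + sigma for the one-sided Exponential) and the
    location gamma for the mean-free Cauchy. With gamma = 0, Cauchy noise is
    the only family that leaves nothing to adjust for."""
    if spec.family == "exponential":
        return spec.gamma + spec.sigma
    return spec.gamma


def add_noise_to_params(params: ParameterVector, spec: NoiseSpec,
                        rng: np.random.Generator,
                        noise: np.ndarray | None = None) -> ParameterVector:
    """Additive noise on a parameter vector; the input is left untouched.

    ``noise`` (flat, test hook) overrides sampling when given.
    """
    flat = params.flatten()
    if noise is None:
        noise = sample_noise(spec, flat.shape, rng)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != flat.shape:
        raise ValueError("noise shape does not match flat parameter length")
    noisy = params.unflatten(flat + noise)
    noisy.role = "noisy_" + params.role
    return noisy


def add_noise_to_transmission(transmission, spec: NoiseSpec,
                              rng: np.random.Generator,
                              noise: np.ndarray | None = None) -> NoisyTransmissionRecord:
    """Additive noise on a transmitted array (smashed activations or a
    gradient array); labels and metadata are never perturbed."""
    if isinstance(transmission, SmashedBatch):
        original = transmission.activations
        meta = {"client_id": transmission.client_id, "kind": "activations"}
    else:
        original = np.asarray(transmission, dtype=np.float64)
        meta = {"kind": "gradients"}
    if noise is None:
        noise = sample_noise(spec, original.shape, rng)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != original.shape:
        raise ValueError("noise shape does not match transmission shape")
    return NoisyTransmissionRecord(original=original, noise=noise,
                                   noisy=original + noise, metadata=meta)


def noisy_transmission(smashed: SmashedBatch, spec: NoiseSpec,
                       rng: np.random.Generator) -> SmashedBatch:
    """Convenience: a SmashedBatch whose activations carry fresh noise."""
    rec = add_noise_to_transmission(smashed, spec, rng)
    return replace(smashed, activations=rec.noisy)


def noisy_update(theta: ParameterVector, grads: ParameterVector | np.ndarray,
                 lr: float, spec: NoiseSpec, rng: np.random.Generator,
                 noise: np.ndarray | None = None) -> ParameterVector:
    """One noisy plain-gradient step: theta - lr * grad + noise.

    Written for SGD mode; the noise term (Cauchy by default) lands directly in
    the parameter update.
    """
    flat = theta.flatten()
    gflat = grads.flatten() if isinstance(grads, ParameterVector) else \
        np.asarray(grads, dtype=np.float64).ravel()
    if gflat.shape != flat.shape:
        raise ValueError("gradient length does not match parameter length")
    if noise is None:
        noise = sample_noise(spec, flat.shape, rng)
    noise = np.asarray(noise, dtype=np.float64)
    return theta.unflatten(flat - lr * gflat + noise)


def restore_parameters(state) -> None:
    """Reinstate the pristine (pre-noise) client parameters on a federated
    state; raises if no pristine copy was stashed. No-op when DP is off but a
    stash exists from a zero-noise dry run."""
    if getattr(state, "pristine_client_params", None) is None:
        raise RuntimeError("no pristine parameter copy to restore")
    for model, pv in zip(state.client_models, state.pristine_client_params,
                         strict=True):
        pv.apply_to(model.client)
    state.pristine_client_params = None
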