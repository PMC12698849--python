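"""Classification metrics, report serialization, and the noise-type sweep.

Metric math delegates to scikit-learn (confusion matrix, per-class
precision/recall/F1 with the zero-division-as-zero convention); this module
owns the report container, lossless JSON/CSV round-trips, and the
privacy/utility sweep over noise families and scales.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .attack import AttackResult, candidate_gradients
from .data import LabeledImageSet, partition, train_test_split_set
from .dp import NoiseSpec, noise_center, sample_noise
from .protocol import TrainConfig, train


@dataclass
class MetricsReport:
    """Confusion matrix plus the usual per-class and averaged metrics."""

    confusion: np.ndarray          # rows = true class
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    @property
    def n_classes(self) -> int:
        return len(self.support)

    def to_frame(self) -> pd.DataFrame:
        """Per-class table in classification-report layout."""
        return pd.DataFrame({"precision": self.precision, "recall": self.recall,
                             "f1": self.f1, "support": self.support})

    def to_dict(self) -> dict:
        return {"kind": "metrics_report",
                "confusion": self.confusion.tolist(),
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
                "accuracy": self.accuracy,
                "macro": {"precision": self.macro_precision,
                          "recall": self.macro_recall, "f1": self.macro_f1},
                "weighted": {"precision": self.weighted_precision,
                             "recall": self.weighted_recall,
                             "f1": self.weighted_f1}}

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(confusion=np.asarray(d["confusion"]),
                   precision=np.asarray(d["precision"]),
                   recall=np.asarray(d["recall"]), f1=np.asarray(d["f1"]),
                   support=np.asarray(d["support"]), accuracy=d["accuracy"],
                   macro_precision=d["macro"]["precision"],
                   macro_recall=d["macro"]["recall"], macro_f1=d["macro"]["f1"],
                   weighted_precision=d["weighted"]["precision"],
                   weighted_recall=d["weighted"]["recall"],
                   weighted_f1=d["weighted"]["f1"])


def compute_metrics(true_labels, predicted_labels, n_classes: int) -> MetricsReport:
    """Standard multi-class metrics; a class with zero predicted positives
    gets precision 0 (and analogously recall)."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("true and predicted label lists differ in length")
    if len(y) == 0:
        raise ValueError("no samples to score")
    labels = np.arange(n_classes)
    cm = confusion_matrix(y, p, labels=labels)
    prec, rec, f1, sup = precision_recall_fscore_support(
        y, p, labels=labels, zero_division=0)
    mprec, mrec, mf1, _ = precision_recall_fscore_support(
        y, p, labels=labels, average="macro", zero_division=0)
    wprec, wrec, wf1, _ = precision_recall_fscore_support(
        y, p, labels=labels, average="weighted", zero_division=0)
    return MetricsReport(confusion=cm, precision=prec, recall=rec, f1=f1,
                         support=sup, accuracy=float((y == p).mean()),
                         macro_precision=float(mprec), macro_recall=float(mrec),
                         macro_f1=float(mf1), weighted_precision=float(wprec),
                         weighted_recall=float(wrec), weighted_f1=float(wf1))


@dataclass
class SweepResult:
    """Privacy/utility sweep rows: one per (family, sigma, seed), plus a
    no-noise baseline row."""

    frame: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": "sweep_result", "config": self.config,
                "rows": self.frame.to_dict(orient="records")}


def run_noise_sweep(base_cfg: TrainConfig, families: list[str],
                    scales: list[float], seeds: list[int],
                    data: Optional[LabeledImageSet] = None,
                    n_attack: int = 100, gamma: float = 0.0,
                    mode: str = "observation",
                    test_fraction: float = 0.2,
                    debias: bool = True,
                    out_path: Optional[str] = None) -> SweepResult:
    """Attack accuracy (and model accuracy) across noise families and scales.

    ``mode="observation"`` (default): train once per seed without noise, then
    apply fresh transmission noise to the recorded per-sample gradients for
    every (family, sigma) — identical in distribution to recording noisy
    gradients directly, at a fraction of the cost. ``mode="retrain"`` trains a
    separate model per configuration with the noise active during training.
    Rows are flushed to ``out_path`` (CSV) as they are produced.
    """
    from .data import generate_synthetic_images

    if mode not in ("observation", "retrain"):
        raise ValueError("mode must be 'observation' or 'retrain'")
    if data is None:
        data = generate_synthetic_images(200, base_cfg.n_classes,
                                         base_cfg.image_size, seed=base_cfg.seed)
    if data.value_range != (-1.0, 1.0):
        from .data import preprocess

        data = preprocess(data)
    rows: list[dict] = []

    def flush() -> None:
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, index=False)

    label_set = list(range(base_cfg.n_classes))
    for seed in seeds:
        cfg = TrainConfig.from_dict({**base_cfg.to_dict(), "seed": int(seed)})
        train_set, test_set = train_test_split_set(data, test_fraction, seed=seed)
        plan = partition(train_set, cfg.n_clients, seed=seed)
        state, history = train(train_set, plan, cfg, eval_data=test_set)
        model_acc = history[-1].get("accuracy", float("nan"))
        subset = test_set.subset(np.arange(min(n_attack, len(test_set))))
        if mode == "observation":
            obs, cand = candidate_gradients(state.model(), subset, label_set)
            diffs = obs[:, None, :] - cand          # (n, C, p): clean residuals
            base_mse = (diffs ** 2).mean(axis=2)
            inferred = np.asarray(label_set)[np.argmin(base_mse, axis=1)]
            rows.append({"family": "none", "gamma": 0.0, "sigma": 0.0,
                         "seed": int(seed), "model_accuracy": model_acc,
                         "attack_accuracy":
                             float((inferred == subset.labels).mean())})
            flush()
            noise_rng = np.random.default_rng([int(seed), 5])
            for family in families:
                for sigma in scales:
                    spec = NoiseSpec(family=family, gamma=gamma,
                                     sigma=float(sigma), targets=("gradients",))
                    noise = sample_noise(spec, obs.shape, noise_rng)
                    if debias:
                        noise = noise - noise_center(spec)
                    mses = ((diffs + noise[:, None, :]) ** 2).mean(axis=2)
                    inferred = np.asarray(label_set)[np.argmin(mses, axis=1)]
                    rows.append({"family": family, "gamma": gamma,
                                 "sigma": float(sigma), "seed": int(seed),
                                 "model_accuracy": model_acc,
                                 "attack_accuracy":
                                     float((inferred == subset.labels).mean())})
                    flush()
        else:
            from .attack import AttackConfig, run_attack

            base = run_attack(state, subset,
                              AttackConfig(n_samples=n_attack, seed=seed))
            rows.append({"family": "none", "gamma": 0.0, "sigma": 0.0,
                         "seed": int(seed), "model_accuracy": model_acc,
                         "attack_accuracy": base.accuracy})
            flush()
            for family in families:
                for sigma in scales:
                    spec = NoiseSpec(family=family, gamma=gamma,
                                     sigma=float(sigma),
                                     targets=("activations", "gradients"))
                    ncfg = TrainConfig.from_dict(
                        {**cfg.to_dict(), "noise": spec.to_dict()})
                    nstate, nhist = train(train_set, plan, ncfg,
                                          eval_data=test_set)
                    res = run_attack(
                        nstate, subset,
                        AttackConfig(n_samples=n_attack, seed=seed, noise=spec))
                    rows.append({"family": family, "gamma": gamma,
                                 "sigma": float(sigma), "seed": int(seed),
                                 "model_accuracy":
                                     nhist[-1].get("accuracy", float("nan")),
                                 "attack_accuracy": res.accuracy})
                    flush()
    frame = pd.DataFrame(rows)
    return SweepResult(frame=frame,
                       config={"families": list(families),
                               "scales": [float(s) for s in scales],
                               "seeds": [int(s) for s in seeds],
                               "gamma": gamma, "mode": mode,
                               "n_attack": n_attack,
                               "train": base_cfg.to_dict()})


# minimal shipped schema for JSON reports: required keys and their types
REPORT_SCHEMA = {
    "metrics_report": {"confusion": list, "precision": list, "recall": list,
                       "f1": list, "support": list, "accuracy": (int, float),
                       "macro": dict, "weighted": dict},
    "attack_result": {"accuracy": (int, float), "inferred": list,
                      "true_labels": list, "mses": list,
                      "n_grad_evals": int},
    "sweep_result": {"config": dict, "rows": list},
}


def validate_report_dict(d: dict) -> None:
    """Check a serialized report against the shipped schema; raises
    ``ValueError`` on a missing key or wrong type."""
    kind = d.get("kind")
    if kind not in REPORT_SCHEMA:
        raise ValueError(f"unknown report kind {kind!r}")
    for key, typ in REPORT_SCHEMA[kind].items():
        if key not in d:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(d[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")


def write_report(report, path: str) -> None:
    """Lossless serialization: JSON for metric/attack reports, CSV for sweep
    rows (with a JSON sidecar carrying the sweep config)."""
    d = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(d):
        raise OSError(f"unwritable path (missing directory): {path}")
    if isinstance(report, SweepResult) and path.endswith(".csv"):
        report.frame.to_csv(path, index=False)
        with open(path[:-4] + ".config.json", "w") as fh:
            json.dump(report.config, fh, indent=2)
        return
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    validate_report_dict(payload)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_report(path: str):
    """Inverse of :func:`write_report`; reproduces all numbers exactly."""
    if path.endswith(".csv"):
        frame = pd.read_csv(path)
        cfg_path = path[:-4] + ".config.json"
        config = {}
        if os.path.exists(cfg_path):
            with open(cfg_path) as fh:
                config = json.load(fh)
        return SweepResult(frame=frame, config=config)
    with open(path) as fh:
        d = json.load(fh)
    validate_report_dict(d)
    if d["kind"] == "metrics_report":
        return MetricsReport.from_dict(d)
    if d["kind"] == "attack_result":
        return AttackResult(inferred=np.asarray(d["inferred"]),
                            true_labels=np.asarray(d["true_labels"]),
                            mses=np.asarray(d["mses"]),
                            n_grad_evals=d["n_grad_evals"])
    return SweepResult(frame=pd.DataFrame(d["rows"]), config=d["config"])
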