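"""Autoencoder novelty gate over the CNN's deep features.

A mirror-symmetric autoencoder (default 512-256-128-64-128-256-512,
leaky-rectified hidden layers, linear output) is trained by mean squared
error on *target-class* deep features only.  At decision time a feature
vector x is scored by

    error(x) = 1 - rho(x, AE(x)),

the complement of the Pearson correlation between the input and its
reconstruction (range [0, 2]; 0 means perfect reconstruction).  Per-class
thresholds tau_c are set on a validation split at a preset recall factor r:
tau_c is the smallest class-c validation error covering at least a
fraction r of class-c samples (the ceil(r*n_c)-th order statistic).  A test
sample predicted as class c is accepted iff error <= tau_c, otherwise
rejected as an unrelated movement.  Ties at the threshold accept, which is
what makes the recall guarantee exact on the calibration set.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .classifier import FEATURE_DIM, CnnClassifier, DeepFeature

DEFAULT_WIDTHS = (512, 256, 128, 64, 128, 256, 512)


class RejectorError(ValueError):
    pass


@dataclass(frozen=True)
class AutoencoderSpec:
    widths: tuple[int, ...] = DEFAULT_WIDTHS
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        w = tuple(self.widths)
        object.__setattr__(self, "widths", w)
        if w[0] != w[-1]:
            raise RejectorError(f"first and last widths must match, got {w[0]} and {w[-1]}")
        if list(w) != list(reversed(w)):
            raise RejectorError(f"widths must be palindromic (mirror architecture), got {w}")
        if len(w) < 3:
            raise RejectorError("autoencoder needs at least one hidden layer")


class Autoencoder:
    def __init__(self, spec: AutoencoderSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        widths = spec.widths
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            layers.append(nn.Dense(a, b, rng))
            if i < len(widths) - 2:  # hidden layers only; output stays linear
                layers.append(nn.LeakyReLU(spec.leaky_slope))
        self.net = nn.Sequential(layers)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self.net.forward(x, train=False)


def train_autoencoder(
    features: Sequence[DeepFeature] | np.ndarray,
    spec: AutoencoderSpec = AutoencoderSpec(),
    epochs: int = 1000,
    learning_rate: float = 1e-4,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[Autoencoder, list[float]]:
    """Seeded Adam minimisation of mean squared reconstruction error.

    ``features`` must hold target-class deep features only; the CNN that
    produced them is never touched here.  Returns the trained autoencoder
    and the per-epoch MSE history (length = epochs).
    """
    x = _as_matrix(features)
    if x.shape[0] == 0:
        raise RejectorError("cannot train the autoencoder on an empty feature set")
    if x.shape[1] != spec.widths[0]:
        raise RejectorError(f"features are {x.shape[1]}-wide; autoencoder expects {spec.widths[0]}")

    ae = Autoencoder(spec, seed=seed)
    optim = nn.Adam(ae.net, lr=learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n = x.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        sse = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = x[idx]
            yb = ae.net.forward(xb, train=True)
            diff = yb - xb
            sse += float(np.sum(diff * diff))
            # d(mean over batch of mean-square residual)/dy
            ae.net.backward(2.0 * diff / diff.size)
            optim.step()
        history.append(sse / x.size)
    return ae, history


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise RejectorError("Pearson correlation undefined for a constant vector")
    return float(dx @ dy) / denom


def reconstruction_error(ae: Autoencoder, feature: np.ndarray | DeepFeature) -> float:
    """1 - Pearson(x, AE(x)); in [0, 2].  Constant inputs degrade to the maximum 2."""
    x = feature.vector if isinstance(feature, DeepFeature) else np.asarray(feature, dtype=float)
    y = ae.reconstruct(x)[0]
    try:
        return 1.0 - pearson(x, y)
    except RejectorError:
        warnings.warn(
            "constant feature or reconstruction: Pearson undefined, scoring maximal error 2.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 2.0


def recall_quantile(errors: Sequence[float], r: float) -> float:
    """Smallest error covering at least a fraction r of the samples."""
    e = np.sort(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise RejectorError("cannot take a recall quantile of an empty error set")
    if not 0.0 < r <= 1.0:
        raise RejectorError(f"recall factor must lie in (0, 1], got {r}")
    k = math.ceil(r * e.size)  # 1-based order statistic
    return float(e[k - 1])


@dataclass
class RejectionModel:
    ae: Autoencoder
    recall_factor: float
    thresholds: dict[str, float]  # per-target-class tau_c
    global_threshold: float
    use_global: bool = False
    cnn_fingerprint: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.recall_factor <= 1.0:
            raise RejectorError(f"recall factor must lie in (0, 1], got {self.recall_factor}")
        for c, tau in self.thresholds.items():
            if tau < 0:
                raise RejectorError(f"threshold for class {c!r} is negative")

    def threshold_for(self, label: str) -> float:
        if self.use_global:
            return self.global_threshold
        if label not in self.thresholds:
            raise RejectorError(f"no calibrated threshold for class {label!r}")
        return self.thresholds[label]


@dataclass
class Decision:
    verdict: str  # "accept" | "reject"
    label: str | None  # CNN class when accepted, None when rejected
    error: float

    @property
    def accepted(self) -> bool:
        return self.verdict == "accept"


def calibrate_thresholds(
    ae: Autoencoder,
    validation_features: dict[str, Sequence[DeepFeature] | np.ndarray],
    recall_factor: float,
    use_global: bool = False,
    cnn: CnnClassifier | None = None,
) -> RejectionModel:
    """Per-class recall-quantile thresholds from validation reconstruction errors.

    ``validation_features`` maps each target class to its validation deep
    features.  The pooled errors also yield a single global threshold for
    the optional one-cutoff mode.
    """
    thresholds: dict[str, float] = {}
    pooled: list[float] = []
    for label, feats in validation_features.items():
        mat = _as_matrix(feats)
        if mat.shape[0] == 0:
            raise RejectorError(f"validation set for class {label!r} is empty")
        errors = [reconstruction_error(ae, v) for v in mat]
        thresholds[label] = recall_quantile(errors, recall_factor)
        pooled.extend(errors)
    if not thresholds:
        raise RejectorError("validation_features is empty")
    return RejectionModel(
        ae=ae,
        recall_factor=recall_factor,
        thresholds=thresholds,
        global_threshold=recall_quantile(pooled, recall_factor),
        use_global=use_global,
        cnn_fingerprint=cnn.fingerprint() if cnn is not None else None,
    )


def decide(cnn_output: DeepFeature, model: RejectionModel) -> Decision:
    """Accept with the CNN label iff the error is at or below the class threshold."""
    e = reconstruction_error(model.ae, cnn_output)
    c = cnn_output.predicted_class
    if e <= model.threshold_for(c):
        return Decision(verdict="accept", label=c, error=e)
    return Decision(verdict="reject", label=None, error=e)


def save_rejection_model(model: RejectionModel, path: str | Path) -> None:
    meta = {
        "widths": list(model.ae.spec.widths),
        "leaky_slope": model.ae.spec.leaky_slope,
        "recall_factor": model.recall_factor,
        "thresholds": model.thresholds,
        "global_threshold": model.global_threshold,
        "use_global": model.use_global,
        "cnn_fingerprint": model.cnn_fingerprint,
    }
    np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **model.ae.net.state_arrays())


def load_rejection_model(
    path: str | Path,
    cnn: CnnClassifier | None = None,
    force: bool = False,
) -> RejectionModel:
    """Load a rejection model; refuse a mismatched CNN fingerprint unless forced."""
    with np.load(path) as z:
        meta = json.loads(str(z["__meta__"]))
        ae = Autoencoder(AutoencoderSpec(tuple(meta["widths"]), meta["leaky_slope"]))
        ae.net.load_state_arrays({k: z[k] for k in z.files if k.startswith("layer")})
    fp = meta["cnn_fingerprint"]
    if cnn is not None and fp is not None and cnn.fingerprint() != fp and not force:
        raise RejectorError(
            "rejection model was calibrated against a different CNN checkpoint "
            f"(fingerprint {fp}); pass force=True to override"
        )
    return RejectionModel(
        ae=ae,
        recall_factor=meta["recall_factor"],
        thresholds=meta["thresholds"],
        global_threshold=meta["global_threshold"],
        use_global=meta["use_global"],
        cnn_fingerprint=fp,
    )


def _as_matrix(features: Sequence[DeepFeature] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(np.asarray(features, dtype=float))
    return (
        np.stack([f.vector for f in features])
        if len(features)
        else np.empty((0, FEATURE_DIM))
    )
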