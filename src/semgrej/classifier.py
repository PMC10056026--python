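"""Discriminative feature CNN trained with joint softmax + center loss.

The network maps a 3xTx8 feature image through three convolutions
(16x2/stride 2/pad 0, 8x3/stride (2,1)/pad (2,1), 3x3/stride 1/pad 1, all
leaky-rectified) and two fully connected layers to a 512-dimensional deep
feature, with a dropout of 0.2 between the two dense layers during
training; a final linear head produces the M class logits.

Training minimises

    L = L_softmax + lambda * L_center,
    L_center = (1/2N) * sum_i ||x_i - c_{y_i}||^2,

where ``c_j`` are per-class feature centroids maintained alongside the
weights by the damped mini-batch rule

    dc_j = sum_{y_i=j} (c_j - x_i) / (1 + n_j),   c_j <- c_j - alpha * dc_j.

The cross-entropy term separates classes; the center term contracts each
class around its centroid, which is what later makes autoencoder-based
novelty rejection on the features work.  After training the feature
extractor is frozen: the rejection stage never updates CNN weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .preprocessing import FeatureImage

FEATURE_DIM = 512


class ClassifierError(ValueError):
    pass


@dataclass
class CnnArchitecture:
    """Layer plan; kernel/stride/pad follow the (rows over T, channel columns) reading."""

    input_height: int = 53  # T, feature rows per image
    input_width: int = 8  # sEMG channels
    input_planes: int = 3  # RMS / MAV / WL
    conv_channels: tuple[int, int, int] = (32, 64, 64)
    conv_kernels: tuple = ((16, 2), (8, 3), (3, 3))
    conv_strides: tuple = ((2, 2), (2, 1), (1, 1))
    conv_pads: tuple = ((0, 0), (2, 1), (1, 1))
    fc4_width: int = 1024
    feature_dim: int = FEATURE_DIM
    n_classes: int = 7
    leaky_slope: float = 0.01
    dropout_rate: float = 0.2

    def conv_output_shape(self) -> tuple[int, int, int]:
        h, w = self.input_height, self.input_width
        for (kh, kw), (sh, sw), (ph, pw) in zip(self.conv_kernels, self.conv_strides, self.conv_pads):
            h = nn.conv_output_size(h, kh, sh, ph)
            w = nn.conv_output_size(w, kw, sw, pw)
            if h < 1 or w < 1:
                raise ClassifierError(f"input {self.input_height}x{self.input_width} too small for conv stack")
        return self.conv_channels[-1], h, w


@dataclass
class ClassCenters:
    """Per-class deep-feature centroids c_j and their update rate alpha."""

    centers: np.ndarray  # [M x feature_dim]
    alpha: float = 0.5

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if not 0.0 < self.alpha < 1.0:
            raise ClassifierError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not np.all(np.isfinite(self.centers)):
            raise ClassifierError("centers must be finite")

    @classmethod
    def zeros(cls, n_classes: int, feature_dim: int = FEATURE_DIM, alpha: float = 0.5) -> "ClassCenters":
        return cls(centers=np.zeros((n_classes, feature_dim)), alpha=alpha)


@dataclass
class TrainConfig:
    lam: float = 0.00025  # center-loss weight lambda
    alpha: float = 0.5  # center update rate
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    standardize_planes: bool = False  # optional per-plane z-scoring, off by default

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ClassifierError("lambda must be >= 0")
        if self.batch_size < 1:
            raise ClassifierError("batch_size must be >= 1")


@dataclass
class DeepFeature:
    vector: np.ndarray  # 512-d fc5 activation
    predicted_class: str
    probabilities: np.ndarray  # length-M simplex vector
    label: str | None = None  # ground truth if known
    kind: str | None = None


def softmax_cross_entropy(logits: np.ndarray, labels: Sequence[int]) -> float:
    """Mean over the batch of -log softmax probability of the true class."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.asarray(labels, dtype=int)
    m = logits.shape[1]
    if labels.size and (labels.min() < 0 or labels.max() >= m):
        raise ClassifierError(f"labels must lie in [0, {m}), got range [{labels.min()}, {labels.max()}]")
    logp = nn.log_softmax(logits)
    return float(-logp[np.arange(len(labels)), labels].mean())


def softmax_cross_entropy_grad(logits: np.ndarray, labels: Sequence[int]) -> np.ndarray:
    """d(mean CE)/d(logits) = (softmax - onehot) / N."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.asarray(labels, dtype=int)
    g = nn.softmax(logits)
    g[np.arange(len(labels)), labels] -= 1.0
    return g / len(labels)


def center_loss(features: np.ndarray, labels: Sequence[int], centers: ClassCenters) -> float:
    """(1/2N) * sum_i ||x_i - c_{y_i}||^2 (non-negative)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] == 0:
        raise ClassifierError("center_loss needs a non-empty batch")
    diff = features - centers.centers[labels]
    return float(0.5 * np.mean(np.sum(diff * diff, axis=1)))


def center_loss_grad(features: np.ndarray, labels: Sequence[int], centers: ClassCenters) -> np.ndarray:
    """Exact gradient of the implemented loss: (x_i - c_{y_i}) / N."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    return (features - centers.centers[labels]) / features.shape[0]


def update_centers(centers: ClassCenters, features: np.ndarray, labels: Sequence[int]) -> ClassCenters:
    """Damped mini-batch centroid update; classes absent from the batch keep their center."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    new = centers.centers.copy()
    for j in np.unique(labels):
        mask = labels == j
        delta = np.sum(new[j] - features[mask], axis=0) / (1.0 + mask.sum())
        new[j] = new[j] - centers.alpha * delta
    return ClassCenters(centers=new, alpha=centers.alpha)


def joint_loss(
    logits: np.ndarray,
    features: np.ndarray,
    labels: Sequence[int],
    centers: ClassCenters,
    lam: float,
) -> float:
    return softmax_cross_entropy(logits, labels) + lam * center_loss(features, labels, centers)


class CnnClassifier:
    """Trained CNN: frozen feature extractor plus linear class head."""

    def __init__(self, arch: CnnArchitecture, class_names: Sequence[str], seed: int = 0) -> None:
        self.arch = arch
        self.class_names = list(class_names)
        if len(self.class_names) != arch.n_classes:
            raise ClassifierError(
                f"{len(self.class_names)} class names for {arch.n_classes} output units"
            )
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        in_ch = arch.input_planes
        for out_ch, k, s, p in zip(arch.conv_channels, arch.conv_kernels, arch.conv_strides, arch.conv_pads):
            layers += [nn.Conv2d(in_ch, out_ch, k, s, p, rng), nn.LeakyReLU(arch.leaky_slope)]
            in_ch = out_ch
        c, h, w = arch.conv_output_shape()
        layers += [
            nn.Flatten(),
            nn.Dense(c * h * w, arch.fc4_width, rng),
            nn.LeakyReLU(arch.leaky_slope),
            nn.Dropout(arch.dropout_rate, rng),
            nn.Dense(arch.fc4_width, arch.feature_dim, rng),
            nn.LeakyReLU(arch.leaky_slope),
        ]
        self.backbone = nn.Sequential(layers)
        self.head = nn.Dense(arch.feature_dim, arch.n_classes, rng)
        self.net = nn.Sequential([self.backbone, self.head])
        self.standardize_planes = False
        self._plane_mean = np.zeros(arch.input_planes)
        self._plane_sd = np.ones(arch.input_planes)

    # -- data plumbing -------------------------------------------------
    def _to_batch(self, images: Sequence[FeatureImage]) -> np.ndarray:
        x = np.stack([im.planes for im in images])  # [N,3,T,8]
        expect = (self.arch.input_planes, self.arch.input_height, self.arch.input_width)
        if x.shape[1:] != expect:
            raise ClassifierError(f"image shape {x.shape[1:]} does not match architecture input {expect}")
        if self.standardize_planes:
            x = (x - self._plane_mean[None, :, None, None]) / self._plane_sd[None, :, None, None]
        return x

    def encode_labels(self, images: Sequence[FeatureImage]) -> np.ndarray:
        index = {n: i for i, n in enumerate(self.class_names)}
        try:
            return np.array([index[im.label] for im in images], dtype=int)
        except KeyError as exc:
            raise ClassifierError(f"unknown class label {exc.args[0]!r}") from exc

    # -- inference -----------------------------------------------------
    def forward_batch(self, images: Sequence[FeatureImage], train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        x = self._to_batch(images)
        feats = self.backbone.forward(x, train=train)
        logits = self.head.forward(feats, train=train)
        return feats, logits

    def forward(self, image: FeatureImage) -> DeepFeature:
        feats, logits = self.forward_batch([image], train=False)
        probs = nn.softmax(logits)[0]
        return DeepFeature(
            vector=feats[0],
            predicted_class=self.class_names[int(np.argmax(probs))],
            probabilities=probs,
            label=image.label,
            kind=image.kind,
        )

    def extract_features(self, images: Sequence[FeatureImage]) -> list[DeepFeature]:
        """Inference-mode deep features (dropout off, deterministic)."""
        if not images:
            return []
        feats, logits = self.forward_batch(images, train=False)
        probs = nn.softmax(logits)
        preds = np.argmax(probs, axis=1)
        return [
            DeepFeature(
                vector=feats[i],
                predicted_class=self.class_names[int(preds[i])],
                probabilities=probs[i],
                label=im.label,
                kind=im.kind,
            )
            for i, im in enumerate(images)
        ]

    def fingerprint(self) -> str:
        """Cheap content hash so a rejection model can detect a foreign CNN."""
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.net.state_arrays()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.net.state_arrays()[name]).tobytes())
        return h.hexdigest()[:16]

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "arch": asdict(self.arch),
            "class_names": self.class_names,
            "standardize_planes": self.standardize_planes,
        }
        np.savez_compressed(
            path,
            __meta__=np.array(json.dumps(meta)),
            plane_mean=self._plane_mean,
            plane_sd=self._plane_sd,
            **self.net.state_arrays(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CnnClassifier":
        with np.load(path) as z:
            meta = json.loads(str(z["__meta__"]))
            arch_doc = meta["arch"]
            for key in ("conv_channels", "conv_kernels", "conv_strides", "conv_pads"):
                arch_doc[key] = tuple(tuple(v) if isinstance(v, list) else v for v in arch_doc[key])
            model = cls(CnnArchitecture(**arch_doc), meta["class_names"])
            model.net.load_state_arrays({k: z[k] for k in z.files if k.startswith("layer")})
            model.standardize_planes = meta["standardize_planes"]
            model._plane_mean = z["plane_mean"]
            model._plane_sd = z["plane_sd"]
        return model


@dataclass
class EpochRecord:
    epoch: int
    ce_loss: float
    center_loss: float
    joint_loss: float
    train_accuracy: float


def train_cnn(
    images: Sequence[FeatureImage],
    cfg: TrainConfig,
    arch: CnnArchitecture | None = None,
    log_path: str | Path | None = None,
) -> tuple[CnnClassifier, ClassCenters, list[EpochRecord]]:
    """Mini-batch Adam on the joint loss with per-batch center updates.

    Weights step first on d(CE)/dW + lambda * d(L_center)/dW (the center
    term's feature gradient is injected at fc5), then the centers move by
    the damped centroid rule.  All randomness (init, shuffling, dropout)
    derives from ``cfg.seed``.
    """
    class_names = sorted({im.label for im in images})
    if len(class_names) < 2:
        raise ClassifierError(f"training needs >= 2 classes, got {class_names}")
    if arch is None:
        t = images[0].planes.shape[1]
        arch = CnnArchitecture(input_height=t, n_classes=len(class_names))
    model = CnnClassifier(arch, class_names, seed=cfg.seed)
    if cfg.standardize_planes:
        x_all = np.stack([im.planes for im in images])
        model.standardize_planes = True
        model._plane_mean = x_all.mean(axis=(0, 2, 3))
        model._plane_sd = np.maximum(x_all.std(axis=(0, 2, 3)), 1e-12)

    labels = model.encode_labels(images)
    centers = ClassCenters.zeros(arch.n_classes, arch.feature_dim, alpha=cfg.alpha)
    optim = nn.Adam(model.net, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    n = len(images)
    history: list[EpochRecord] = []
    log_lines: list[str] = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        ce_sum = cl_sum = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [images[i] for i in idx]
            y = labels[idx]
            feats, logits = model.forward_batch(batch, train=True)

            ce = softmax_cross_entropy(logits, y)
            cl = center_loss(feats, y, centers)
            ce_sum += ce * len(idx)
            cl_sum += cl * len(idx)
            correct += int((np.argmax(logits, axis=1) == y).sum())

            dlogits = softmax_cross_entropy_grad(logits, y)
            dfeats = model.head.backward(dlogits)
            dfeats = dfeats + cfg.lam * center_loss_grad(feats, y, centers)
            model.backbone.backward(dfeats)
            optim.step()
            centers = update_centers(centers, feats, y)

        rec = EpochRecord(
            epoch=epoch,
            ce_loss=ce_sum / n,
            center_loss=cl_sum / n,
            joint_loss=ce_sum / n + cfg.lam * cl_sum / n,
            train_accuracy=correct / n,
        )
        history.append(rec)
        log_lines.append(json.dumps(asdict(rec)))

    if log_path is not None:
        Path(log_path).write_text("\n".join(log_lines) + "\n")
    return model, centers, history
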