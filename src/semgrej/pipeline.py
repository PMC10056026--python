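"""End-to-end orchestration: simulate -> preprocess -> split -> train -> calibrate -> evaluate.

The split follows the recording protocol's evaluation design: target-class
feature images are class-stratified 60/20/20 into train/validation/test
(largest-remainder rounding, so partition sizes are exact), while *every*
unrelated-movement image goes to the test set only — the classifier and
the autoencoder must never see the movements they are later asked to
reject.  All stages are seeded and deterministic; each run emits a
manifest listing the config snapshot, seeds, artifact hashes and wall
times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import preprocessing as pp
from . import rejector as rj
from .classifier import CnnClassifier, DeepFeature, TrainConfig, train_cnn
from .evaluation import OpenSetReport, open_set_confusion, roc_auc
from .preprocessing import FeatureImage
from .rejector import AutoencoderSpec, RejectionModel, calibrate_thresholds, decide, train_autoencoder
from .synthetic import (
    SimulationConfig,
    default_movement_set,
    generate_recording,
    write_recording_csv,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class SplitSpec:
    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    stratify: bool = True
    per_subject: bool = False
    seed: int = 0
    min_per_class: int = 5

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if min(fracs) <= 0:
            raise PipelineError(f"split fractions must be positive, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise PipelineError(f"split fractions must sum to 1, got {sum(fracs)}")


def _largest_remainder(n: int, fracs: Sequence[float]) -> list[int]:
    """Integer partition of n proportional to fracs, summing exactly to n."""
    quotas = [n * f for f in fracs]
    sizes = [int(q) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(range(len(fracs)), key=lambda i: quotas[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def split_dataset(
    images: Sequence[FeatureImage],
    spec: SplitSpec,
) -> tuple[list[FeatureImage], list[FeatureImage], list[FeatureImage]]:
    """Class-stratified seeded split; unrelated images go to test only."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    targets = [im for im in images if im.kind != "unrelated"]
    unrelated = [im for im in images if im.kind == "unrelated"]

    groups: dict[str, list[FeatureImage]] = {}
    for im in targets:
        key = im.label if spec.stratify else "__all__"
        if spec.per_subject:
            key = f"{im.subject}/{key}"
        groups.setdefault(key, []).append(im)

    train: list[FeatureImage] = []
    val: list[FeatureImage] = []
    test: list[FeatureImage] = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) < spec.min_per_class:
            raise PipelineError(
                f"class {key!r} has only {len(members)} images; "
                f"need at least {spec.min_per_class} to split"
            )
        order = rng.permutation(len(members))
        n_tr, n_va, n_te = _largest_remainder(
            len(members), (spec.train, spec.validation, spec.test)
        )
        shuffled = [members[i] for i in order]
        train.extend(shuffled[:n_tr])
        val.extend(shuffled[n_tr : n_tr + n_va])
        test.extend(shuffled[n_tr + n_va :])
    test.extend(unrelated)
    return train, val, test


@dataclass
class AeConfig:
    widths: tuple[int, ...] = rj.DEFAULT_WIDTHS
    epochs: int = 1000
    learning_rate: float = 1e-4
    batch_size: int = 32


@dataclass
class PipelineConfig:
    """Single config document covering every stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window_len_ms: float = pp.DEFAULT_WINDOW_MS
    step_ms: float = pp.DEFAULT_STEP_MS
    stack: int = pp.DEFAULT_STACK
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    ae: AeConfig = field(default_factory=AeConfig)
    recall_factor: float = 0.9
    use_global_threshold: bool = False
    seed: int = 0

    def resolve_seeds(self) -> "PipelineConfig":
        """Derive all stage seeds from the master seed for one-knob reproducibility."""
        self.simulation.seed = self.seed
        self.split.seed = self.seed + 1
        self.train.seed = self.seed + 2
        return self

    def to_json(self) -> str:
        doc = asdict(self)
        doc["simulation"] = json.loads(self.simulation.to_json())
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        doc = json.loads(text)
        sim = SimulationConfig.from_json(json.dumps(doc.pop("simulation")))
        split = SplitSpec(**doc.pop("split"))
        train = TrainConfig(**doc.pop("train"))
        ae_doc = doc.pop("ae")
        ae_doc["widths"] = tuple(ae_doc["widths"])
        return cls(simulation=sim, split=split, train=train, ae=AeConfig(**ae_doc), **doc)

    @classmethod
    def defaults_json(cls) -> str:
        return cls().to_json()

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    config: dict
    seeds: dict[str, int]
    artifacts: dict[str, str]  # path -> sha256
    timings_s: dict[str, float]
    metrics: dict

    def write(self, path: str | Path) -> None:
        doc = asdict(self)
        for p in self.artifacts:
            if not Path(p).exists():
                raise PipelineError(f"manifest references missing artifact {p}")
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    report: OpenSetReport
    manifest: RunManifest
    model: CnnClassifier
    rejection: RejectionModel


def _stage(name: str, fn, timings: dict[str, float]):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 4)
    return out


def evaluate_open_set(
    model: CnnClassifier,
    rejection: RejectionModel,
    test_images: Sequence[FeatureImage],
) -> OpenSetReport:
    """Score every test image through the CNN + rejection gate and report."""
    feats = model.extract_features(test_images)
    decisions = [decide(f, rejection) for f in feats]
    truths = [(im.label, im.kind == "unrelated") for im in test_images]
    report = open_set_confusion(truths, decisions, class_names=model.class_names)
    errors = [d.error for d in decisions]
    unrel = [im.kind == "unrelated" for im in test_images]
    if any(unrel) and not all(unrel):
        report.roc_points, report.auc = roc_auc(errors, unrel)
    return report


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Execute the whole workflow; optionally persist artifacts + manifest."""
    config.resolve_seeds()
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def say(msg: str) -> None:
        if verbose:
            print(f"[semgrej] {msg}", flush=True)

    say(f"simulate: seed={config.simulation.seed}")
    recording = _stage("simulate", lambda: generate_recording(config.simulation), timings)

    say("preprocess: windows + feature images")

    def _preprocess():
        images, threshold = pp.encode_recording(
            recording,
            window_len_ms=config.window_len_ms,
            step_ms=config.step_ms,
            stack=config.stack,
        )
        for im in images:
            im.subject = recording.subject_id
        return images, threshold

    images, threshold = _stage("preprocess", _preprocess, timings)

    say(f"split: {len(images)} images, fractions "
        f"{config.split.train}/{config.split.validation}/{config.split.test}")
    train_set, val_set, test_set = _stage(
        "split", lambda: split_dataset(images, config.split), timings
    )

    say(f"train-cnn: {len(train_set)} images, lambda={config.train.lam}, "
        f"{config.train.epochs} epochs")
    model, centers, history = _stage(
        "train-cnn", lambda: train_cnn(train_set, config.train), timings
    )

    say("train-ae: target deep features")

    def _train_ae():
        train_feats = model.extract_features(train_set)
        return train_autoencoder(
            train_feats,
            spec=AutoencoderSpec(widths=config.ae.widths),
            epochs=config.ae.epochs,
            learning_rate=config.ae.learning_rate,
            batch_size=config.ae.batch_size,
            seed=config.train.seed,
        )

    ae, ae_history = _stage("train-ae", _train_ae, timings)

    say(f"calibrate: recall factor {config.recall_factor}")

    def _calibrate():
        val_feats = model.extract_features(val_set)
        by_class: dict[str, list[DeepFeature]] = {}
        for f in val_feats:
            by_class.setdefault(f.label, []).append(f)
        return calibrate_thresholds(
            ae,
            by_class,
            config.recall_factor,
            use_global=config.use_global_threshold,
            cnn=model,
        )

    rejection = _stage("calibrate", _calibrate, timings)

    say(f"evaluate: {len(test_set)} test images")
    report = _stage(
        "evaluate", lambda: evaluate_open_set(model, rejection, test_set), timings
    )

    if out is not None:
        write_recording_csv(recording, out / "signals.csv", out / "trials.csv")
        pp.save_images(out / "images.npz", images)
        model.save(out / "cnn.npz")
        rj.save_rejection_model(rejection, out / "rejection.npz")
        report.write(out / "report.json", out / "report.txt")
        (out / "train_log.jsonl").write_text(
            "\n".join(json.dumps(asdict(r)) for r in history) + "\n"
        )
        for p in sorted(out.iterdir()):
            if p.name != "manifest.json":
                artifacts[str(p)] = _sha256(p)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        config=json.loads(config.to_json()),
        seeds={
            "master": config.seed,
            "simulation": config.simulation.seed,
            "split": config.split.seed,
            "train": config.train.seed,
        },
        artifacts=artifacts,
        timings_s=timings,
        metrics=json.loads(report.to_json()),
    )
    if out is not None:
        manifest.write(out / "manifest.json")
    say(
        f"done: target acc {report.sample_target_accuracy:.3f}, "
        f"rejection {report.rejection_rate:.3f}, AUC {report.auc}"
    )
    return PipelineResult(report=report, manifest=manifest, model=model, rejection=rejection)


def sweep_recall(
    config: PipelineConfig,
    recalls: Sequence[float] = (0.8, 0.85, 0.9),
) -> dict[float, OpenSetReport]:
    """Re-calibrate and re-evaluate one trained model across recall factors."""
    config.resolve_seeds()
    base = run_pipeline(config)
    model = base.model
    ae = base.rejection.ae

    # rebuild the validation split exactly as the run did
    recording = generate_recording(config.simulation)
    images, _ = pp.encode_recording(
        recording, config.window_len_ms, config.step_ms, config.stack
    )
    _, val_set, test_set = split_dataset(images, config.split)
    val_feats = model.extract_features(val_set)
    by_class: dict[str, list[DeepFeature]] = {}
    for f in val_feats:
        by_class.setdefault(f.label, []).append(f)

    out: dict[float, OpenSetReport] = {}
    for r in recalls:
        rejection = calibrate_thresholds(
            ae, by_class, r, use_global=config.use_global_threshold, cnn=model
        )
        out[r] = evaluate_open_set(model, rejection, test_set)
    return out


def sweep_lambda(
    config: PipelineConfig,
    lambdas: Sequence[float] = (0.0, 2.5e-4),
) -> dict[float, OpenSetReport]:
    """Retrain end-to-end at each center-loss weight and compare reports."""
    out: dict[float, OpenSetReport] = {}
    for lam in lambdas:
        cfg = PipelineConfig.from_json(config.to_json())
        cfg.train.lam = lam
        out[lam] = run_pipeline(cfg).report
    return out
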