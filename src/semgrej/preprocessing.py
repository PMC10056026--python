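"""Windowing, muscle-activity detection, and time-domain feature images.

The raw 8-channel signal is cut into overlapping analysis windows (250 ms
length, 100 ms step at 200 Hz -> 50x8 matrices).  Windows are flagged active
when their mean rectified amplitude exceeds the neutral-state threshold
mu + 3*sigma (both statistics taken over the rectified neutral signal,
population form).  Each active window is reduced to a 3x8 feature row --
per-channel RMS, MAV and waveform length -- and T consecutive rows are
stacked into a 3xTx8 "feature image" for the CNN (T defaults to 53).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic import EmgRecording, N_CHANNELS, NEUTRAL, REST, Trial

DEFAULT_WINDOW_MS = 250.0
DEFAULT_STEP_MS = 100.0
DEFAULT_STACK = 53  # feature rows per image


class PreprocessingError(ValueError):
    pass


@dataclass
class AnalysisWindow:
    samples: np.ndarray  # [window_len x 8]
    label: str
    kind: str
    trial_id: int
    active: bool = False

    @property
    def mean_rectified(self) -> float:
        return float(np.abs(self.samples).mean())


@dataclass(frozen=True)
class ActivityThreshold:
    """Neutral-derived activity gate: threshold = mu + 3*sigma."""

    mu_neutral: float
    sigma_neutral: float

    @property
    def threshold(self) -> float:
        return self.mu_neutral + 3.0 * self.sigma_neutral


@dataclass
class FeatureImage:
    """3xTx8 stack of per-window RMS / MAV / WL feature rows."""

    planes: np.ndarray  # [3 x T x 8]; plane 0=RMS, 1=MAV, 2=WL
    label: str
    kind: str
    trial_id: int
    pad_count: int = 0  # rows filled by repeating the last real row
    subject: str = ""

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] != 3 or self.planes.shape[2] != N_CHANNELS:
            raise PreprocessingError(f"feature image must be 3xTx{N_CHANNELS}, got {self.planes.shape}")


def rms(x: Sequence[float] | np.ndarray) -> float:
    """Root mean square: sqrt((1/N) * sum(x_n^2))."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise PreprocessingError("rms requires at least 1 sample")
    return float(np.sqrt(np.mean(np.square(x))))


def mav(x: Sequence[float] | np.ndarray) -> float:
    """Mean absolute value: (1/N) * sum(|x_n|)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise PreprocessingError("mav requires at least 1 sample")
    return float(np.mean(np.abs(x)))


def wl(x: Sequence[float] | np.ndarray) -> float:
    """Waveform length: sum(|x_n - x_{n-1}|)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise PreprocessingError("wl requires at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def fit_activity_threshold(neutral_samples: Sequence[float] | np.ndarray) -> ActivityThreshold:
    """Mean/std of the rectified neutral signal (population standard deviation)."""
    x = np.abs(np.asarray(neutral_samples, dtype=float)).ravel()
    if x.size < 2:
        raise PreprocessingError("need at least 2 neutral samples to fit the threshold")
    return ActivityThreshold(mu_neutral=float(x.mean()), sigma_neutral=float(x.std(ddof=0)))


def is_active(window: AnalysisWindow, th: ActivityThreshold) -> bool:
    """Strictly above the neutral threshold counts as muscle activity."""
    return window.mean_rectified > th.threshold


def window_counts(n: int, length: int, step: int) -> int:
    """Number of stride-`step` windows of `length` samples in an n-sample trial."""
    if n < length:
        return 0
    return (n - length) // step + 1


def segment_windows(
    recording: EmgRecording,
    window_len_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    include_rest: bool = False,
) -> list[AnalysisWindow]:
    """Cut overlapping windows inside each trial (never across boundaries).

    Trials shorter than one window yield no windows.  Rest intervals are
    skipped unless ``include_rest`` is set.
    """
    rate = recording.sampling_rate
    length_f = window_len_ms * rate / 1000.0
    step_f = step_ms * rate / 1000.0
    length, step = int(round(length_f)), int(round(step_f))
    if abs(length_f - length) > 1e-9 or abs(step_f - step) > 1e-9:
        raise PreprocessingError(
            f"window ({window_len_ms} ms) and step ({step_ms} ms) must map to "
            f"whole samples at {rate} Hz"
        )
    if length < 1 or step < 1:
        raise PreprocessingError("window and step must be at least one sample")

    windows: list[AnalysisWindow] = []
    for trial_id, trial in enumerate(recording.trials):
        if trial.kind == REST and not include_rest:
            continue
        seg = recording.trial_samples(trial)
        for k in range(window_counts(len(seg), length, step)):
            start = k * step
            windows.append(
                AnalysisWindow(
                    samples=seg[start : start + length],
                    label=trial.label,
                    kind=trial.kind,
                    trial_id=trial_id,
                )
            )
    return windows


def mark_activity(
    windows: Iterable[AnalysisWindow],
    th: ActivityThreshold,
    neutral_exempt: bool = True,
) -> list[AnalysisWindow]:
    """Set each window's ``active`` flag against the neutral threshold.

    The neutral class *is* the rest state, so its windows can never exceed a
    threshold calibrated on neutral data; with ``neutral_exempt`` (default)
    neutral-labelled windows are kept active so the class stays trainable.
    """
    out = []
    for w in windows:
        w.active = is_active(w, th) or (neutral_exempt and w.kind == NEUTRAL)
        out.append(w)
    return out


def feature_row(window: AnalysisWindow) -> np.ndarray:
    """Per-channel [3 x 8] feature row (RMS, MAV, WL) of one window."""
    s = window.samples
    return np.stack(
        [
            np.sqrt(np.mean(np.square(s), axis=0)),
            np.mean(np.abs(s), axis=0),
            np.sum(np.abs(np.diff(s, axis=0)), axis=0),
        ]
    )


def encode_feature_images(
    windows: Sequence[AnalysisWindow],
    stack: int = DEFAULT_STACK,
) -> list[FeatureImage]:
    """Stack consecutive active windows of one trial into 3xTx8 images.

    With ``m`` active windows and stack depth ``T``: stride-1 stacking gives
    ``m - T + 1`` images; a short trial (m < T) yields a single image padded
    by repeating its last feature row (the pad count is recorded).
    """
    if stack < 1:
        raise PreprocessingError("stack depth must be >= 1")
    active = [w for w in windows if w.active]
    if not active:
        return []
    trial_ids = {w.trial_id for w in active}
    labels = {w.label for w in active}
    if len(trial_ids) > 1 or len(labels) > 1:
        raise PreprocessingError(
            "encode_feature_images expects windows from a single trial/label; "
            f"got trials {sorted(trial_ids)} labels {sorted(labels)}"
        )
    rows = np.stack([feature_row(w) for w in active])  # [m x 3 x 8]
    m = len(rows)
    label, kind, tid = active[0].label, active[0].kind, active[0].trial_id

    images: list[FeatureImage] = []
    if m >= stack:
        for start in range(m - stack + 1):
            planes = np.transpose(rows[start : start + stack], (1, 0, 2))
            images.append(FeatureImage(planes=planes, label=label, kind=kind, trial_id=tid))
    else:
        pad = np.repeat(rows[-1:], stack - m, axis=0)
        planes = np.transpose(np.concatenate([rows, pad]), (1, 0, 2))
        images.append(
            FeatureImage(planes=planes, label=label, kind=kind, trial_id=tid, pad_count=stack - m)
        )
    return images


def encode_recording(
    recording: EmgRecording,
    window_len_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    stack: int = DEFAULT_STACK,
    threshold: ActivityThreshold | None = None,
) -> tuple[list[FeatureImage], ActivityThreshold]:
    """Full preprocessing of a recording into labelled feature images.

    The activity threshold is fit on the neutral-class signal of the
    recording itself unless one is supplied (e.g. from a training session).
    """
    if threshold is None:
        neutral = [
            recording.trial_samples(t)
            for t in recording.trials
            if t.kind == NEUTRAL
        ]
        if not neutral:  # fall back to rest intervals
            neutral = [recording.trial_samples(t) for t in recording.trials if t.kind == REST]
        if not neutral:
            raise PreprocessingError("no neutral or rest signal to fit the activity threshold")
        threshold = fit_activity_threshold(np.concatenate(neutral))

    windows = mark_activity(segment_windows(recording, window_len_ms, step_ms), threshold)
    by_trial: dict[int, list[AnalysisWindow]] = {}
    for w in windows:
        by_trial.setdefault(w.trial_id, []).append(w)

    images: list[FeatureImage] = []
    for tid in sorted(by_trial):
        images.extend(encode_feature_images(by_trial[tid], stack=stack))
    return images, threshold


def save_images(path: str | Path, images: Sequence[FeatureImage]) -> None:
    """Lossless NPZ archive of feature images with labels and trial ids."""
    np.savez_compressed(
        path,
        planes=np.stack([im.planes for im in images]) if images else np.empty((0, 3, DEFAULT_STACK, N_CHANNELS)),
        labels=np.array([im.label for im in images], dtype=str),
        kinds=np.array([im.kind for im in images], dtype=str),
        trial_ids=np.array([im.trial_id for im in images], dtype=int),
        pad_counts=np.array([im.pad_count for im in images], dtype=int),
        subjects=np.array([im.subject for im in images], dtype=str),
    )


def load_images(path: str | Path) -> list[FeatureImage]:
    with np.load(path) as z:
        return [
            FeatureImage(
                planes=z["planes"][i],
                label=str(z["labels"][i]),
                kind=str(z["kinds"][i]),
                trial_id=int(z["trial_ids"][i]),
                pad_count=int(z["pad_counts"][i]),
                subject=str(z["subjects"][i]) if "subjects" in z.files else "",
            )
            for i in range(len(z["labels"]))
        ]
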