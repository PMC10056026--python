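"""Seeded synthetic 8-channel sEMG generator.

Emulates a Myo-armband style recording protocol: each movement is performed
as a series of repetitions of band-limited (20-95 Hz at a 200 Hz rate),
zero-mean noise whose per-channel standard deviation encodes which muscles
the movement activates, separated by rest intervals of baseline noise.
Target movements have near-orthogonal activation patterns; "unrelated"
movements are convex mixtures of two target patterns, deliberately similar
to the vocabulary the classifier is trained on, so that open-set rejection
is non-trivial.

Nothing here claims physiological fidelity (no motor-unit model, no
force/kinematics); the generator exists so that every downstream stage is
testable without external recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

N_CHANNELS = 8

TARGET = "target"
UNRELATED = "unrelated"
NEUTRAL = "neutral"
REST = "rest"

_VALID_KINDS = (TARGET, UNRELATED, NEUTRAL)


class SimulationError(ValueError):
    """Raised when a simulation config violates an invariant."""


@dataclass(frozen=True)
class MovementSpec:
    """One movement class: a name, its kind, and per-channel gains."""

    name: str
    kind: str
    activation: np.ndarray  # 8 non-negative per-channel gains
    base_amplitude: float = 1.0

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        object.__setattr__(self, "activation", act)
        if act.shape != (N_CHANNELS,):
            raise SimulationError(
                f"activation for {self.name!r} must have exactly {N_CHANNELS} "
                f"entries, got shape {act.shape}"
            )
        if np.any(act < 0):
            raise SimulationError(f"activation for {self.name!r} has negative gains")
        if self.kind not in _VALID_KINDS:
            raise SimulationError(
                f"kind must be one of {_VALID_KINDS}, got {self.kind!r}"
            )
        if self.base_amplitude < 0:
            raise SimulationError(f"base_amplitude for {self.name!r} is negative")

    @property
    def is_target(self) -> bool:
        # the neutral class is part of the target vocabulary
        return self.kind in (TARGET, NEUTRAL)


@dataclass
class SimulationConfig:
    """Recording protocol parameters (defaults mirror the Myo protocol)."""

    sampling_rate: float = 200.0  # Hz
    repetition_s: float = 5.0
    rest_s: float = 3.0
    repetitions: int = 6
    noise_sd: float = 0.05  # baseline (rest) noise, arbitrary units
    seed: int = 0
    movements: Sequence[MovementSpec] = field(default_factory=lambda: default_movement_set())

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise SimulationError("sampling_rate must be > 0")
        if self.repetition_s < 0:
            raise SimulationError("repetition_s must be >= 0")
        if self.rest_s < 0:
            raise SimulationError("rest_s must be >= 0")
        if self.repetitions < 1:
            raise SimulationError("repetitions must be >= 1")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not self.movements:
            raise SimulationError("movements list is empty")

    def to_json(self) -> str:
        doc = {
            "sampling_rate": self.sampling_rate,
            "repetition_s": self.repetition_s,
            "rest_s": self.rest_s,
            "repetitions": self.repetitions,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "movements": [
                {
                    "name": m.name,
                    "kind": m.kind,
                    "activation": m.activation.tolist(),
                    "base_amplitude": m.base_amplitude,
                }
                for m in self.movements
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        doc = json.loads(text)
        movements = [
            MovementSpec(
                name=m["name"],
                kind=m["kind"],
                activation=np.asarray(m["activation"], dtype=float),
                base_amplitude=m.get("base_amplitude", 1.0),
            )
            for m in doc.pop("movements")
        ]
        return cls(movements=movements, **doc)


@dataclass
class Trial:
    start: int  # inclusive, 0-based
    end: int  # exclusive
    label: str
    kind: str


@dataclass
class EmgRecording:
    """Raw multichannel signal plus per-trial interval labels."""

    samples: np.ndarray  # [time x 8]
    sampling_rate: float
    trials: list[Trial]
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise SimulationError(
                f"samples must be [time x {N_CHANNELS}], got {self.samples.shape}"
            )
        n = self.samples.shape[0]
        prev_end = 0
        for t in sorted(self.trials, key=lambda t: t.start):
            if not (0 <= t.start <= t.end <= n):
                raise SimulationError(f"trial {t} outside sample range [0, {n})")
            if t.start < prev_end:
                raise SimulationError(f"trial {t} overlaps a previous trial")
            prev_end = t.end

    def trial_samples(self, trial: Trial) -> np.ndarray:
        return self.samples[trial.start : trial.end]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def default_movement_set(
    similarity_band: tuple[float, float] = (0.5, 0.95),
    neutral_gain: float = 0.02,
    pattern_seed: int = 12345,
) -> list[MovementSpec]:
    """Seven target movements (incl. neutral) and five unrelated movements.

    The six active targets get near-orthogonal activations: a dominant
    channel plus a weaker secondary two channels away, mimicking a primary
    muscle with crosstalk.  Each unrelated movement is a convex mixture of
    two target activations plus a small seeded perturbation, with the mixing
    weight solved (by bisection) so that its cosine similarity to the most
    similar target lands inside ``similarity_band``.  Raising the band's
    upper edge therefore makes the open-set problem strictly harder.
    """
    lo, hi = similarity_band
    if not (0.0 < lo < hi <= 1.0):
        raise SimulationError(f"similarity band {similarity_band} must satisfy 0 < lo < hi <= 1")
    rng = np.random.default_rng(pattern_seed)

    targets: list[MovementSpec] = []
    for k in range(6):
        act = np.full(N_CHANNELS, 0.05)
        act[k] = 1.0
        act[(k + 2) % N_CHANNELS] += 0.30
        targets.append(MovementSpec(name=f"T{k + 1}", kind=TARGET, activation=act))

    max_gain = max(float(m.activation.max()) for m in targets)
    neutral = MovementSpec(
        name="neutral",
        kind=NEUTRAL,
        activation=np.full(N_CHANNELS, neutral_gain * max_gain),
    )

    # unrelated movements: mixtures of target pairs, tuned into the band
    pairs = [(0, 1), (2, 3), (4, 5), (1, 4), (3, 0)]
    desired = np.linspace(lo + 0.6 * (hi - lo), lo + 0.9 * (hi - lo), len(pairs))
    unrelated: list[MovementSpec] = []
    for (ia, ib), target_cos in zip(pairs, desired):
        ta, tb = targets[ia].activation, targets[ib].activation
        perturb = rng.uniform(0.0, 0.08, size=N_CHANNELS)

        def sim(w: float) -> float:
            mix = w * ta + (1.0 - w) * tb + perturb
            return max(cosine_similarity(mix, t.activation) for t in targets)

        # sim(w) is continuous; its max over targets at w=0.5 is near the
        # pair's mutual overlap and rises toward 1 as w -> 0 or 1.
        w_lo, w_hi = 0.5, 1.0
        if sim(w_lo) > target_cos:
            w = w_lo  # already above the requested point; clamp inside band
        else:
            for _ in range(60):
                w = 0.5 * (w_lo + w_hi)
                if sim(w) < target_cos:
                    w_lo = w
                else:
                    w_hi = w
            w = 0.5 * (w_lo + w_hi)
        mix = w * ta + (1.0 - w) * tb + perturb
        unrelated.append(
            MovementSpec(name=f"R{len(unrelated) + 1}", kind=UNRELATED, activation=mix)
        )

    specs = targets + [neutral] + unrelated
    _check_band(specs, lo, hi)
    return specs


def _check_band(specs: Sequence[MovementSpec], lo: float, hi: float) -> None:
    targets = [m for m in specs if m.kind == TARGET]
    for m in specs:
        if m.kind != UNRELATED:
            continue
        best = max(cosine_similarity(m.activation, t.activation) for t in targets)
        if not (lo - 1e-9 <= best <= hi + 1e-9):
            raise SimulationError(
                f"unrelated movement {m.name!r} has max target cosine {best:.3f} "
                f"outside band [{lo}, {hi}]"
            )


def _band_noise(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Unit-variance noise shaped to the 20-95 Hz sEMG band, [n x 8]."""
    white = rng.standard_normal((n, N_CHANNELS))
    nyq = rate / 2.0
    hi = min(95.0, 0.98 * nyq)
    lo = min(20.0, 0.5 * hi)
    if n > 30:  # sosfiltfilt needs some padding room; tiny segments stay white
        sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
        white = sosfiltfilt(sos, white, axis=0)
    sd = white.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return white / sd


def _envelope(n: int, rate: float, ramp_s: float = 0.2) -> np.ndarray:
    """Trapezoidal on/off envelope with 200 ms ramps (clipped for short trials)."""
    ramp = min(int(round(ramp_s * rate)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[n - ramp :] = np.linspace(1.0, 0.0, ramp + 1)[1:]
    return env


def generate_recording(config: SimulationConfig, subject_id: str = "synthetic") -> EmgRecording:
    """Simulate one recording session: every movement x repetition, plus rests.

    For each repetition of each movement the generator emits ``repetition_s``
    seconds of band-shaped zero-mean noise whose per-channel standard
    deviation is ``base_amplitude * activation[ch] + noise_sd``, under a
    trapezoidal onset/offset envelope, followed by ``rest_s`` seconds of
    baseline noise (sd = ``noise_sd``).  Fully reproducible from the seed.
    """
    config.validate()
    rate = config.sampling_rate
    n_rep = int(round(config.repetition_s * rate))
    n_rest = int(round(config.rest_s * rate))
    rng = np.random.default_rng(config.seed)

    chunks: list[np.ndarray] = []
    trials: list[Trial] = []
    cursor = 0
    for spec in config.movements:
        sd = spec.base_amplitude * spec.activation + config.noise_sd
        for _ in range(config.repetitions):
            if n_rep > 0:
                active = _band_noise(rng, n_rep, rate) * sd
                active *= _envelope(n_rep, rate)[:, None]
                chunks.append(active)
                trials.append(Trial(cursor, cursor + n_rep, spec.name, spec.kind))
                cursor += n_rep
            if n_rest > 0:
                rest = _band_noise(rng, n_rest, rate) * config.noise_sd
                chunks.append(rest)
                trials.append(Trial(cursor, cursor + n_rest, REST, REST))
                cursor += n_rest

    samples = np.vstack(chunks) if chunks else np.empty((0, N_CHANNELS))
    return EmgRecording(samples=samples, sampling_rate=rate, trials=trials, subject_id=subject_id)


def write_recording_csv(rec: EmgRecording, signal_path: str | Path, trials_path: str | Path) -> None:
    """Write the signal (``t,ch1..ch8``) and the trial table as CSV sidecars."""
    n = rec.samples.shape[0]
    df = pd.DataFrame(rec.samples, columns=[f"ch{i + 1}" for i in range(N_CHANNELS)])
    df.insert(0, "t", np.arange(n) / rec.sampling_rate)
    df.to_csv(signal_path, index=False)
    tdf = pd.DataFrame(
        {
            "trial_id": np.arange(len(rec.trials)),
            "start": [t.start for t in rec.trials],
            "end": [t.end for t in rec.trials],
            "label": [t.label for t in rec.trials],
            "kind": [t.kind for t in rec.trials],
            "subject": rec.subject_id,
        }
    )
    tdf.to_csv(trials_path, index=False)


def read_recording_csv(signal_path: str | Path, trials_path: str | Path) -> EmgRecording:
    df = pd.read_csv(signal_path)
    chans = [f"ch{i + 1}" for i in range(N_CHANNELS)]
    t = df["t"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 200.0
    tdf = pd.read_csv(trials_path)
    trials = [
        Trial(int(r.start), int(r.end), str(r.label), str(r.kind))
        for r in tdf.itertuples()
    ]
    subject = str(tdf["subject"].iloc[0]) if len(tdf) else "unknown"
    return EmgRecording(
        samples=df[chans].to_numpy(),
        sampling_rate=round(rate, 6),
        trials=trials,
        subject_id=subject,
    )
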