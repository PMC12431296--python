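"""Synthetic inputs with the statistical structure the pipeline assumes.

**EEG.** Motor imagery attenuates (event-related desynchronization, ERD) the
mu (~10 Hz) and beta (~20 Hz) rhythms over class-specific sensorimotor
channels.  The generator emits trials of 1/f (pink) background noise plus
mu/beta sinusoids whose *power* is reduced by a configurable per-class,
per-channel attenuation during the imagery interval.  Contralateral hand
classes get strong ERD over the lateral channel groups, legs a moderate
midline ERD, tongue a weak bilateral beta ERD — mirroring the expectation
that hand imagery is the easiest to decode.

**Detections.** Scenes are separable through anchor objects (bed/bedroom,
oven/kitchen, couch+tv/living room) with scene-conditional presence
probabilities, category-specific spatial priors over the image (e.g. beds in
the lower-central region) and Beta-distributed confidences; shared
distractor categories (person, chair, dining table) appear in every scene.

Both generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preproc import EEGRecording, EpochSet
from .scenefeat import Detection, DetectionSet

# 22-channel motor-cortex-centred 10-10 montage
DEFAULT_CHANNELS = [
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
]

# per class: channel -> (mu power attenuation, beta power attenuation)
DEFAULT_ERD_MAP: dict[int, dict[str, tuple[float, float]]] = {
    0: {"C4": (0.7, 0.6), "C6": (0.6, 0.5), "CP4": (0.5, 0.4),
        "FC4": (0.4, 0.4)},                              # left hand -> right cortex
    1: {"C3": (0.7, 0.6), "C5": (0.6, 0.5), "CP3": (0.5, 0.4),
        "FC3": (0.4, 0.4)},                              # right hand -> left cortex
    2: {"Cz": (0.5, 0.35), "CPz": (0.45, 0.3), "FCz": (0.4, 0.3)},  # legs
    3: {"C3": (0.0, 0.3), "C4": (0.0, 0.3), "C1": (0.2, 0.2),
        "C2": (0.2, 0.2)},                               # tongue (weak, bilateral)
}


@dataclass
class EEGSimSpec:
    """Parameters of the motor-imagery EEG simulator."""

    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    fs: float = 250.0
    epoch_t0_s: float = -0.2          # cue-relative first sample
    epoch_t1_s: float = 4.0
    imagery_start_s: float = 0.5      # ERD onset after the cue
    n_classes: int = 4
    erd_map: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_ERD_MAP.items()})
    mu_freq_hz: float = 10.0
    beta_freq_hz: float = 20.0
    mu_amp: float = 1.2
    beta_amp: float = 0.8
    noise_amp: float = 1.8            # pink-noise std (uV)
    amp_jitter: float = 0.2           # per-trial uniform amplitude jitter +-20%

    def __post_init__(self) -> None:
        for c, chans in self.erd_map.items():
            for ch, (a_mu, a_beta) in chans.items():
                if ch not in self.channel_names:
                    raise ValueError(f"ERD channel {ch!r} not in montage")
                if not (0 <= a_mu <= 1 and 0 <= a_beta <= 1):
                    raise ValueError("attenuations must lie in [0, 1]")

    @property
    def planted_channels(self) -> list[str]:
        """Non-core channels carrying class-dependent ERD (montage order)."""
        core = {"C3", "Cz", "C4"}
        planted = {ch for chans in self.erd_map.values() for ch in chans}
        return [c for c in self.channel_names if c in planted - core]


def pink_noise(rng: np.random.Generator, n: int, size: tuple = ()) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(size + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def generate_mi_eeg(spec: EEGSimSpec, n_trials: int,
                    seed: int | np.random.Generator = 0) -> EpochSet:
    """Generate ``n_trials`` labelled epochs (classes drawn round-robin).

    Each epoch spans ``[epoch_t0_s, epoch_t1_s)`` cue-relative; the class's
    ERD attenuation multiplies the band sinusoid *power* (amplitude scaled by
    ``sqrt(1 - a)``) from ``imagery_start_s`` onward.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = spec.fs
    n_samp = int(round((spec.epoch_t1_s - spec.epoch_t0_s) * fs))
    t = spec.epoch_t0_s + np.arange(n_samp) / fs
    imagery = t >= spec.imagery_start_s
    nch = len(spec.channel_names)

    labels = np.arange(n_trials) % spec.n_classes
    rng.shuffle(labels)
    data = np.empty((n_trials, nch, n_samp))
    for tr in range(n_trials):
        cls = int(labels[tr])
        erd = spec.erd_map.get(cls, {})
        x = spec.noise_amp * pink_noise(rng, n_samp, (nch,))
        jit = 1.0 + spec.amp_jitter * (2 * rng.random(nch) - 1)
        for ci, ch in enumerate(spec.channel_names):
            a_mu, a_beta = erd.get(ch, (0.0, 0.0))
            for freq, amp, att in ((spec.mu_freq_hz, spec.mu_amp, a_mu),
                                   (spec.beta_freq_hz, spec.beta_amp, a_beta)):
                phase = rng.uniform(0, 2 * np.pi)
                env = np.where(imagery, np.sqrt(1.0 - att), 1.0)
                x[ci] += amp * jit[ci] * env * np.sin(2 * np.pi * freq * t + phase)
        data[tr] = x
    return EpochSet(data, labels, list(spec.channel_names), fs)


def generate_mi_recording(spec: EEGSimSpec, n_trials: int,
                          seed: int = 0, gap_s: float = 1.0) -> EEGRecording:
    """Concatenate generated epochs into a continuous recording with events."""
    epochs = generate_mi_eeg(spec, n_trials, seed)
    n_samp = epochs.n_samples
    gap = int(round(gap_s * spec.fs))
    pre = int(round(-spec.epoch_t0_s * spec.fs))
    total = n_trials * (n_samp + gap) + gap
    samples = np.zeros((epochs.n_channels, total))
    events = []
    pos = gap
    for tr in range(n_trials):
        samples[:, pos:pos + n_samp] = epochs.data[tr]
        events.append((pos + pre, int(epochs.labels[tr])))
        pos += n_samp + gap
    return EEGRecording(samples, list(spec.channel_names), spec.fs, events)


# ---------------------------------------------------------------------------
# Scene detections

#: (cx mean, cy mean, positional sd) in normalized image coordinates
DEFAULT_SPATIAL_PRIORS: dict[int, tuple[float, float, float]] = {
    59: (0.50, 0.70, 0.08),   # bed: lower central
    69: (0.45, 0.60, 0.10),   # oven
    72: (0.75, 0.45, 0.10),   # refrigerator
    68: (0.55, 0.35, 0.10),   # microwave
    71: (0.40, 0.55, 0.10),   # sink
    57: (0.50, 0.65, 0.10),   # couch
    62: (0.50, 0.30, 0.08),   # tv: upper central
    65: (0.55, 0.60, 0.15),   # remote
    58: (0.20, 0.50, 0.12),   # potted plant
    73: (0.60, 0.50, 0.15),   # book
    74: (0.50, 0.20, 0.10),   # clock: high on the wall
    0:  (0.50, 0.55, 0.20),   # person
    56: (0.45, 0.60, 0.15),   # chair
    60: (0.50, 0.65, 0.12),   # dining table
    45: (0.50, 0.55, 0.12),   # bowl
}

#: per scene: category id -> presence probability
DEFAULT_SCENE_PRIORS: dict[str, dict[int, float]] = {
    "kitchen":     {69: 0.95, 72: 0.85, 68: 0.6, 71: 0.7, 45: 0.5,
                    0: 0.4, 56: 0.6, 60: 0.5},
    "living room": {57: 0.95, 62: 0.85, 65: 0.5, 58: 0.6, 73: 0.4,
                    0: 0.5, 56: 0.6, 60: 0.3},
    "bedroom":     {59: 0.95, 74: 0.45, 73: 0.5, 58: 0.3,
                    0: 0.4, 56: 0.4},
}


@dataclass
class SceneSimSpec:
    """Parameters of the scene-conditional detection simulator."""

    scene_priors: dict[str, dict[int, float]] = field(
        default_factory=lambda: {s: dict(p) for s, p in DEFAULT_SCENE_PRIORS.items()})
    spatial_priors: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SPATIAL_PRIORS))
    image_size: tuple[float, float] = (640.0, 480.0)
    score_beta: tuple[float, float] = (8.0, 2.0)   # mean ~0.8
    extra_count_lambda: float = 0.3                # extra instances beyond 1
    box_frac_range: tuple[float, float] = (0.10, 0.40)

    def __post_init__(self) -> None:
        for scene, priors in self.scene_priors.items():
            for cat, p in priors.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"prior for category {cat} in {scene} "
                                     "is not a probability")

    @property
    def scenes(self) -> list[str]:
        return list(self.scene_priors)


def generate_detections(spec: SceneSimSpec, n_images: int, scene: str,
                        seed: int | np.random.Generator = 0
                        ) -> list[DetectionSet]:
    """Sample per-image detection sets for one scene."""
    if scene not in spec.scene_priors:
        raise ValueError(f"unknown scene {scene!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = spec.image_size
    a, b = spec.score_beta
    out = []
    for i in range(n_images):
        dets = []
        for cat, p in spec.scene_priors[scene].items():
            if rng.random() >= p:
                continue
            count = 1 + rng.poisson(spec.extra_count_lambda)
            cx0, cy0, sd = spec.spatial_priors.get(cat, (0.5, 0.5, 0.2))
            for _ in range(count):
                cx = float(np.clip(rng.normal(cx0, sd), 0.02, 0.98))
                cy = float(np.clip(rng.normal(cy0, sd), 0.02, 0.98))
                bw = rng.uniform(*spec.box_frac_range) * w
                bh = rng.uniform(*spec.box_frac_range) * h
                x = float(np.clip(cx * w - bw / 2, 0, w - 1))
                y = float(np.clip(cy * h - bh / 2, 0, h - 1))
                bw = min(bw, w - x)
                bh = min(bh, h - y)
                score = float(np.clip(rng.beta(a, b), 1e-3, 1.0))
                dets.append(Detection(cat, (x, y, bw, bh), score))
        out.append(DetectionSet(f"{scene}_{i}", (w, h), dets))
    return out


def generate_scene_dataset(spec: SceneSimSpec, n_per_scene: int,
                           seed: int = 0
                           ) -> tuple[list[DetectionSet], np.ndarray]:
    """Balanced multi-scene dataset: detection sets plus scene labels."""
    rng = np.random.default_rng(seed)
    sets: list[DetectionSet] = []
    labels: list[str] = []
    for scene in spec.scenes:
        sets.extend(generate_detections(spec, n_per_scene, scene, rng))
        labels.extend([scene] * n_per_scene)
    return sets, np.asarray(labels, dtype=object)
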