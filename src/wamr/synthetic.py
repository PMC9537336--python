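"""Class-conditional synthetic feature vectors and labelled frame streams.

Stands in for the encoder outputs of a speech front end: one Gaussian
cluster per phone class in feature space, frame streams at a 10 ms hop, and
phone durations drawn from a truncated normal (mean 69.9 ms, s.d. 28.9 ms,
floor of one frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from wamr.evaluation import MEXBET22, PhoneString

HOP_MS = 10.0
DURATION_MEAN_MS = 69.9
DURATION_SD_MS = 28.9

# "peaked" cluster shape: per-dimension discrete offsets around the class
# mean, a dominant mode with moderate side lobes.  Mirrors the sharply
# non-uniform column distributions that encoder outputs produce, and keeps
# every populated quantizer cell well above the iota sensitivity threshold.
_PEAK_OFFSETS = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
DEFAULT_PEAK_MODE_PROB = 0.64


@dataclass
class FrameStream:
    """A sequence of frame vectors (one per 10 ms hop) with optional aligned
    ground-truth class labels."""

    frames: np.ndarray  # (n_frames, n_dims)
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if self.labels is not None and len(self.labels) != len(self.frames):
            raise ValueError("labels must align one-to-one with frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic generator.

    ``separation`` scales the spread of the class means relative to the
    within-class scale ``spread``; larger values give more separable
    classes.  ``profile`` selects balanced or Zipf-like class frequencies.
    ``cluster_shape`` picks the within-class distribution: "gaussian"
    (isotropic normal, s.d. ``spread``) or "peaked" (discrete offsets of
    size ``spread`` around the mean with a dominant mode).
    """

    n_classes: int = 22
    n_dims: int = 32
    separation: float = 5.0
    spread: float = 1.0
    profile: str = "balanced"  # or "zipf"
    cluster_shape: str = "gaussian"  # or "peaked"
    peak_mode_prob: float = DEFAULT_PEAK_MODE_PROB
    duration_mean_ms: float = DURATION_MEAN_MS
    duration_sd_ms: float = DURATION_SD_MS
    hop_ms: float = HOP_MS
    window: int = 8
    seed: int = 0
    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.profile not in ("balanced", "zipf"):
            raise ValueError("profile must be 'balanced' or 'zipf'")
        if self.cluster_shape not in ("gaussian", "peaked"):
            raise ValueError("cluster_shape must be 'gaussian' or 'peaked'")
        if not 0.0 < self.peak_mode_prob < 1.0:
            raise ValueError("peak_mode_prob must lie in (0, 1)")
        if self.labels is None:
            if self.n_classes <= len(MEXBET22):
                self.labels = MEXBET22[: self.n_classes]
            else:
                self.labels = tuple(f"c{i}" for i in range(self.n_classes))
        if len(self.labels) != self.n_classes:
            raise ValueError("labels must have n_classes entries")

    def class_means(self) -> np.ndarray:
        """Deterministic class centroids drawn once from the config seed."""
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.separation, (self.n_classes, self.n_dims))

    def class_frequencies(self) -> np.ndarray:
        if self.profile == "balanced":
            return np.full(self.n_classes, 1.0 / self.n_classes)
        ranks = np.arange(1, self.n_classes + 1, dtype=np.float64)
        freq = 1.0 / ranks
        return freq / freq.sum()


def _draw_cluster(
    cfg: GeneratorConfig, mean: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    if cfg.cluster_shape == "gaussian":
        return mean + rng.normal(0.0, cfg.spread, (count, cfg.n_dims))
    offsets = _PEAK_OFFSETS * cfg.spread
    side = (1.0 - cfg.peak_mode_prob) / 4.0
    probs = np.array([side, side, cfg.peak_mode_prob, side, side])
    picks = rng.choice(len(offsets), size=(count, cfg.n_dims), p=probs)
    return mean + offsets[picks]


def generate_units(
    cfg: GeneratorConfig, label: str, count: int, seed: int
) -> np.ndarray:
    """Draw ``count`` feature vectors from the class cluster of ``label``."""
    idx = cfg.labels.index(label)
    mean = cfg.class_means()[idx]
    return _draw_cluster(cfg, mean, count, np.random.default_rng(seed))


def _draw_duration_frames(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> int:
    """Phone duration in frames: truncated normal in ms (floor one hop),
    rounded to the hop grid."""
    a = (cfg.hop_ms - cfg.duration_mean_ms) / cfg.duration_sd_ms
    d = truncnorm.rvs(
        a, np.inf, loc=cfg.duration_mean_ms, scale=cfg.duration_sd_ms,
        random_state=rng,
    )
    return max(1, int(round(d / cfg.hop_ms)))


def expected_frames_per_phone(cfg: GeneratorConfig) -> float:
    """Analytic mean of the duration model, in frames (ignoring rounding)."""
    a = (cfg.hop_ms - cfg.duration_mean_ms) / cfg.duration_sd_ms
    return float(
        truncnorm.mean(
            a, np.inf, loc=cfg.duration_mean_ms, scale=cfg.duration_sd_ms
        )
        / cfg.hop_ms
    )


def generate_utterance(
    cfg: GeneratorConfig,
    phone_sequence: Sequence[str],
    seed: int,
    durations_ms: Optional[Sequence[float]] = None,
) -> tuple[FrameStream, PhoneString]:
    """Emit a labelled frame stream for a phone sequence.

    Each phone contributes ``round(duration / hop)`` frames (at least one)
    drawn from its class cluster; ``durations_ms`` overrides the stochastic
    duration model (one entry per phone).
    """
    for ph in phone_sequence:
        if ph not in cfg.labels:
            raise ValueError(f"phone {ph!r} not in the generator inventory")
    rng = np.random.default_rng(seed)
    means = cfg.class_means()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    for k, ph in enumerate(phone_sequence):
        if durations_ms is not None:
            n_frames = max(1, int(round(durations_ms[k] / cfg.hop_ms)))
        else:
            n_frames = _draw_duration_frames(cfg, rng)
        mean = means[cfg.labels.index(ph)]
        frames.append(_draw_cluster(cfg, mean, n_frames, rng))
        labels.extend([ph] * n_frames)
    if not frames:
        return (
            FrameStream(np.zeros((0, cfg.n_dims)), labels=[]),
            PhoneString(()),
        )
    return (
        FrameStream(np.vstack(frames), labels=labels),
        PhoneString(tuple(phone_sequence)),
    )


@dataclass
class Utterance:
    stream: FrameStream
    phones: PhoneString

    def units(self) -> tuple[np.ndarray, list[str]]:
        """Unit-level vectors with their labels.  Synthetic frames stand for
        window-level encoder outputs directly, so each frame is a unit."""
        return self.stream.frames, list(self.stream.labels or [])


@dataclass
class Corpus:
    """Disjoint utterance partitions: train / rem / test."""

    train: list[Utterance]
    rem: list[Utterance]
    test: list[Utterance]

    def partition_units(self, name: str) -> tuple[np.ndarray, list[str]]:
        utts = getattr(self, name)
        vecs, labs = [], []
        for u in utts:
            v, l = u.units()
            if len(v):
                vecs.append(v)
                labs.extend(l)
        if not vecs:
            return np.zeros((0, 0)), []
        return np.vstack(vecs), labs


def generate_corpus(
    cfg: GeneratorConfig,
    n_utterances: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    min_phones: int = 5,
    max_phones: int = 15,
) -> Corpus:
    """Generate utterances from a random phone process under the frequency
    profile and partition them 70/20/10 (rounded) into train/rem/test."""
    if n_utterances < 10:
        raise ValueError("need at least 10 utterances to partition")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("partition fractions must sum to 1")
    rng = np.random.default_rng(seed)
    freqs = cfg.class_frequencies()
    utts: list[Utterance] = []
    for _ in range(n_utterances):
        length = int(rng.integers(min_phones, max_phones + 1))
        phones = [
            cfg.labels[i] for i in rng.choice(cfg.n_classes, length, p=freqs)
        ]
        stream, ps = generate_utterance(
            cfg, phones, seed=int(rng.integers(0, 2**31 - 1))
        )
        utts.append(Utterance(stream, ps))
    n_train = int(round(fractions[0] * n_utterances))
    n_rem = int(round(fractions[1] * n_utterances))
    return Corpus(
        train=utts[:n_train],
        rem=utts[n_train : n_train + n_rem],
        test=utts[n_train + n_rem :],
    )
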