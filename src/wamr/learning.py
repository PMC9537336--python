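"""Incremental self-training loop.

Each stage has an active phase — novel frame streams are scanned with a
sliding window, accepted windows are used as retrieval cues, and a
(cue, retrieved) pair is kept when both members fall in the same class — and
a passive phase in which the quantizer, the surrogate classifier and the
registers are rebuilt from the enriched, rebalanced unit pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from wamr.core import RecognitionParams
from wamr.quantization import Quantizer
from wamr.synthetic import FrameStream
from wamr.system import MemorySystem, evaluate_system


class NearestCentroidClassifier:
    """Reference surrogate classifier: nearest class centroid in feature
    space."""

    def __init__(self) -> None:
        self.centroids: Optional[np.ndarray] = None
        self.labels: list[str] = []

    def fit(self, vectors: np.ndarray, labels: Sequence[str]) -> "NearestCentroidClassifier":
        vectors = np.asarray(vectors, dtype=np.float64)
        labels = list(labels)
        if len(vectors) != len(labels) or not len(vectors):
            raise ValueError("need aligned, non-empty vectors and labels")
        self.labels = sorted(set(labels))
        lab_arr = np.asarray(labels, dtype=object)
        self.centroids = np.vstack(
            [vectors[lab_arr == lab].mean(axis=0) for lab in self.labels]
        )
        return self

    def classify(self, v: np.ndarray) -> str:
        if self.centroids is None:
            raise RuntimeError("classifier is not fitted")
        d = np.linalg.norm(self.centroids - np.asarray(v), axis=1)
        return self.labels[int(np.argmin(d))]


def sample_windows(stream: FrameStream, width: int = 8) -> np.ndarray:
    """All contiguous ``width``-frame windows at hop 1, each aggregated to a
    single vector by the frame mean.  Streams shorter than ``width`` yield
    one window centre-padded by edge replication; empty streams yield none.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    frames = stream.frames
    if len(frames) == 0:
        return np.zeros((0, frames.shape[1] if frames.ndim == 2 else 0))
    if len(frames) < width:
        deficit = width - len(frames)
        before = deficit // 2
        after = deficit - before
        padded = np.vstack(
            [np.repeat(frames[:1], before, axis=0), frames,
             np.repeat(frames[-1:], after, axis=0)]
        )
        return padded.mean(axis=0, keepdims=True)
    n = len(frames) - width + 1
    csum = np.vstack([np.zeros((1, frames.shape[1])), np.cumsum(frames, axis=0)])
    return (csum[width:] - csum[:-width]) / width


def window_labels(stream: FrameStream, width: int = 8) -> list[str]:
    """Majority ground-truth label per window (for synthetic streams)."""
    if stream.labels is None:
        raise ValueError("stream carries no ground-truth labels")
    labels = stream.labels
    if len(labels) < width:
        return [Counter(labels).most_common(1)[0][0]] if labels else []
    return [
        Counter(labels[k : k + width]).most_common(1)[0][0]
        for k in range(len(labels) - width + 1)
    ]


@dataclass
class CollectedPair:
    cue: np.ndarray
    retrieved: np.ndarray
    label: str


def active_phase(
    sys: MemorySystem,
    streams: Iterable[FrameStream],
    clf: NearestCentroidClassifier,
    seed: int,
    width: int = 8,
    quotas: Optional[dict[str, int]] = None,
    existing_counts: Optional[dict[str, int]] = None,
    same_class_source: str = "classifier",
) -> list[CollectedPair]:
    """Scan streams window by window; rejected windows are discarded, and a
    recognized window and its retrieval are kept (two units, under the
    decision label) only when both members belong to the same class.

    ``same_class_source`` selects how the class test is done: "classifier"
    applies the surrogate classifier to both members; "decision" compares
    the classifier's label for the retrieved unit against the memory
    decision's label for the cue.  ``quotas`` caps the number of units
    (cue + retrieved each count) added per class on top of
    ``existing_counts``.
    """
    if same_class_source not in ("classifier", "decision"):
        raise ValueError("same_class_source must be 'classifier' or 'decision'")
    rng = np.random.default_rng(seed)
    counts = Counter(existing_counts or {})
    kept: list[CollectedPair] = []
    for stream in streams:
        for w in sample_windows(stream, width):
            decision = sys.recognize_unit(w)
            if decision.rejected:
                continue
            label = decision.chosen
            if quotas is not None and counts[label] + 2 > quotas.get(label, 0):
                continue
            cue_q = sys.quantizer.quantize(w)
            out = sys.registers[label].retrieve(cue_q, sys.params, rng)
            if out is None:
                continue
            retrieved = sys.quantizer.dequantize(out)
            cue_class = clf.classify(w)
            ret_class = clf.classify(retrieved)
            same = (
                cue_class == ret_class
                if same_class_source == "classifier"
                else ret_class == label
            )
            if not same:
                continue
            kept.append(CollectedPair(cue=np.asarray(w), retrieved=retrieved, label=label))
            counts[label] += 2
    return kept


@dataclass(frozen=True)
class BalancePlan:
    """Per-class caps on existing counts and total collection targets."""

    caps: dict[str, int]
    targets: dict[str, int]
    median: float


def balance_quotas(counts: dict[str, int]) -> BalancePlan:
    """Rebalancing rule: classes above the median are capped at the median;
    classes below it may grow to 10% above the median; the rest may add at
    most one tenth of the most represented class."""
    if not counts:
        raise ValueError("need at least one class")
    med = float(np.median(list(counts.values())))
    biggest = max(counts.values())
    caps = {c: int(min(k, round(med))) for c, k in counts.items()}
    targets = {}
    for c, k in counts.items():
        if k < med:
            targets[c] = int(round(1.1 * med))
        else:
            targets[c] = caps[c] + int(round(biggest / 10))
    return BalancePlan(caps=caps, targets=targets, median=med)


@dataclass
class LearnConfig:
    params: RecognitionParams
    n_levels: int = 8
    window: int = 8
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    rebuild: bool = True  # rebuild registers from Rem_s (vs extend)
    same_class_source: str = "classifier"


@dataclass
class StageState:
    system: MemorySystem
    classifier: NearestCentroidClassifier
    pool: tuple[np.ndarray, list[str]]


def _partition(
    vectors: np.ndarray,
    labels: list[str],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
):
    order = rng.permutation(len(vectors))
    n_train = int(round(fractions[0] * len(vectors)))
    n_rem = int(round(fractions[1] * len(vectors)))
    idx_t = order[:n_train]
    idx_r = order[n_train : n_train + n_rem]
    idx_s = order[n_train + n_rem :]
    lab = np.asarray(labels, dtype=object)
    return (
        (vectors[idx_t], list(lab[idx_t])),
        (vectors[idx_r], list(lab[idx_r])),
        (vectors[idx_s], list(lab[idx_s])),
    )


def _setup_stage(
    vectors: np.ndarray,
    labels: list[str],
    all_labels: Sequence[str],
    cfg: LearnConfig,
    rng: np.random.Generator,
) -> tuple[StageState, dict[str, float]]:
    """Passive phase: refit quantizer + classifier on Train, rebuild the
    registers from Rem, measure on Test."""
    (tv, tl), (rv, rl), (sv, sl) = _partition(vectors, labels, cfg.fractions, rng)
    quant = Quantizer.fit(vectors, cfg.n_levels)
    clf = NearestCentroidClassifier().fit(tv, tl)
    sys = MemorySystem.empty(list(all_labels), quant, cfg.params)
    for v, lab in zip(rv, rl):
        sys.register_unit(lab, v)
    metrics = evaluate_system(sys, sv, sl) if len(sv) else {}
    state = StageState(system=sys, classifier=clf, pool=(vectors, labels))
    return state, metrics


def _apply_caps(
    vectors: np.ndarray,
    labels: list[str],
    caps: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    lab = np.asarray(labels, dtype=object)
    keep_idx: list[int] = []
    for c, cap in caps.items():
        idx = np.nonzero(lab == c)[0]
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep_idx.extend(idx.tolist())
    keep_idx.sort()
    return vectors[keep_idx], list(lab[keep_idx])


def imbalance_ratio(labels: Sequence[str]) -> float:
    counts = Counter(labels)
    return max(counts.values()) / max(1, min(counts.values()))


def run_stages(
    initial_vectors: np.ndarray,
    initial_labels: Sequence[str],
    stage_streams: Sequence[Sequence[FrameStream]],
    cfg: LearnConfig,
    seed: int,
    all_labels: Optional[Sequence[str]] = None,
    eval_set: Optional[tuple[np.ndarray, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Run the staged loop; one report row per stage (stage 0 = initial
    state).  Fully deterministic given the seed.

    Per-stage metrics come from the stage's own Test partition; when
    ``eval_set`` is given, each stage's system is additionally measured on
    that fixed held-out set (columns ``eval_*``), which makes recall
    comparable across stages despite the changing class balance of the
    pool.
    """
    initial_vectors = np.asarray(initial_vectors, dtype=np.float64)
    labels = list(initial_labels)
    if all_labels is None:
        all_labels = sorted(set(labels))
    master = np.random.default_rng(seed)
    rows = []

    def _eval_fixed(state: StageState) -> dict[str, float]:
        if eval_set is None:
            return {}
        ev = evaluate_system(state.system, eval_set[0], list(eval_set[1]))
        return {f"eval_{k}": v for k, v in ev.items()}

    state, metrics = _setup_stage(
        initial_vectors, labels, all_labels, cfg, master
    )
    metrics = {**metrics, **_eval_fixed(state)}
    rows.append(
        {"stage": 0, "n_units": len(labels),
         "imbalance": imbalance_ratio(labels), "collected": 0, **metrics}
    )

    for s, streams in enumerate(stage_streams, start=1):
        vectors, labels = state.pool
        if not len(streams):
            rows.append(
                {"stage": s, "n_units": len(labels),
                 "imbalance": imbalance_ratio(labels), "collected": 0,
                 **metrics}
            )
            continue
        plan = balance_quotas(dict(Counter(labels)))
        vectors, labels = _apply_caps(vectors, labels, plan.caps, master)
        pairs = active_phase(
            state.system,
            streams,
            state.classifier,
            seed=int(master.integers(0, 2**31 - 1)),
            width=cfg.window,
            quotas=plan.targets,
            existing_counts=dict(Counter(labels)),
            same_class_source=cfg.same_class_source,
        )
        if pairs:
            new_vecs = np.vstack(
                [np.vstack([p.cue, p.retrieved]) for p in pairs]
            )
            new_labs = [lab for p in pairs for lab in (p.label, p.label)]
            vectors = np.vstack([vectors, new_vecs])
            labels = labels + new_labs
        state, metrics = _setup_stage(vectors, labels, all_labels, cfg, master)
        metrics = {**metrics, **_eval_fixed(state)}
        rows.append(
            {"stage": s, "n_units": len(labels),
             "imbalance": imbalance_ratio(labels),
             "collected": 2 * len(pairs), **metrics}
        )
    return pd.DataFrame(rows)
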