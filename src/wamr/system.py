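"""Ensemble of labelled registers with supervised registration, all-register
recognition, entropy-weighted disambiguation, and the size/fill sweep.

When several registers accept a cue the system chooses the one minimising
``entropy * (1 / rho)`` — low indeterminacy acting as a prior and the cue
weight as a likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from wamr.core import FeatureFunction, RecognitionParams, WeightedAMR
from wamr.evaluation import register_metrics
from wamr.quantization import Quantizer

#: Named recognition-parameter scenarios (iota, kappa, xi, sigma).
SCENARIOS: dict[str, RecognitionParams] = {
    "I": RecognitionParams(0.0, 0.0, 0, 0.5),
    "II": RecognitionParams(0.3, 0.0, 0, 0.5),
    "III": RecognitionParams(0.0, 1.5, 0, 0.5),
    "IV": RecognitionParams(0.0, 0.0, 0, 0.1),
    "V": RecognitionParams(0.3, 1.5, 0, 0.1),
    "VI": RecognitionParams(0.3, 1.5, 1, 0.1),
}

#: Sentinel decision label when no register accepts the cue.
REJECTED = "rejected"


@dataclass
class Decision:
    responders: list[str]
    chosen: str  # a label, or REJECTED
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def rejected(self) -> bool:
        return self.chosen == REJECTED


@dataclass
class MemorySystem:
    """``c`` labelled registers sharing one quantizer and one parameter
    tuple."""

    registers: dict[str, WeightedAMR]
    quantizer: Quantizer
    params: RecognitionParams

    def __post_init__(self) -> None:
        geoms = {(r.n_cols, r.n_rows) for r in self.registers.values()}
        if len(geoms) > 1:
            raise ValueError(f"registers disagree on geometry: {geoms}")
        if geoms:
            n, m = geoms.pop()
            if (n, m) != (self.quantizer.n_dims, self.quantizer.n_levels):
                raise ValueError("quantizer geometry does not match registers")

    @classmethod
    def empty(
        cls,
        labels: Sequence[str],
        quantizer: Quantizer,
        params: RecognitionParams,
    ) -> "MemorySystem":
        regs = {
            lab: WeightedAMR(quantizer.n_dims, quantizer.n_levels, label=lab)
            for lab in labels
        }
        return cls(registers=regs, quantizer=quantizer, params=params)

    # -- unit operations --------------------------------------------------

    def register_unit(self, label: str, v: np.ndarray) -> None:
        if label not in self.registers:
            raise KeyError(f"unknown class label {label!r}")
        self.registers[label].register(self.quantizer.quantize(v))

    def recognize_unit(self, v: np.ndarray) -> Decision:
        """Present the cue to every register; among the accepting ones pick
        the label minimising ``entropy / rho`` (ties broken by label
        order)."""
        if not self.registers:
            raise ValueError("system has no registers")
        cue = self.quantizer.quantize(v)
        return self._decide(cue)

    def _decide(self, cue: FeatureFunction) -> Decision:
        responders: list[str] = []
        scores: dict[str, float] = {}
        for label in sorted(self.registers):
            res = self.registers[label].recognize(cue, self.params)
            if res.accepted:
                responders.append(label)
                scores[label] = (
                    res.entropy / res.rho if res.rho > 0 else math.inf
                )
        if not responders:
            return Decision(responders=[], chosen=REJECTED)
        chosen = min(responders, key=lambda lab: (scores[lab], lab))
        return Decision(responders=responders, chosen=chosen, scores=scores)

    def retrieve_unit(
        self, v: np.ndarray, seed: int | np.random.Generator
    ) -> Optional[tuple[str, np.ndarray]]:
        """Recognize, then reconstruct from the chosen register; returns the
        label and the dequantized vector, or ``None`` on rejection."""
        decision = self.recognize_unit(v)
        if decision.rejected:
            return None
        cue = self.quantizer.quantize(v)
        out = self.registers[decision.chosen].retrieve(cue, self.params, seed)
        if out is None:  # cannot happen: the chosen register accepted
            return None
        return decision.chosen, self.quantizer.dequantize(out)

    # -- bulk helpers ------------------------------------------------------

    @classmethod
    def build(
        cls,
        vectors: np.ndarray,
        labels: Sequence[str],
        all_labels: Sequence[str],
        n_levels: int,
        params: RecognitionParams,
        fit_vectors: np.ndarray | None = None,
    ) -> "MemorySystem":
        """Fit a quantizer (on ``fit_vectors`` if given, else on the stored
        vectors) and register every (vector, label) pair."""
        ref = vectors if fit_vectors is None else fit_vectors
        quant = Quantizer.fit(ref, n_levels)
        sys = cls.empty(list(all_labels), quant, params)
        for v, lab in zip(vectors, labels):
            sys.register_unit(lab, v)
        return sys

    def mean_entropy(self) -> float:
        if not self.registers:
            return 0.0
        return float(
            np.mean([r.entropy()[0] for r in self.registers.values()])
        )


def evaluate_system(
    sys: MemorySystem, vectors: np.ndarray, labels: Sequence[str]
) -> dict[str, float]:
    """Per-register and system precision/recall on labelled test units.

    Per register: a test unit is a positive iff its true label matches the
    register; the register's prediction is its own accept/reject. System
    level: the decision label against the true label, with no true negatives
    (every unit belongs to some class), so accuracy coincides with recall.
    """
    labels = list(labels)
    per_reg = {lab: [0, 0, 0, 0] for lab in sys.registers}  # tp fp tn fn
    sys_tp = sys_fp = sys_fn = 0
    for v, true_lab in zip(vectors, labels):
        cue = sys.quantizer.quantize(v)
        accepted = {}
        for lab in sys.registers:
            accepted[lab] = sys.registers[lab].recognize(cue, sys.params).accepted
            c = per_reg[lab]
            if lab == true_lab:
                if accepted[lab]:
                    c[0] += 1
                else:
                    c[3] += 1
            else:
                if accepted[lab]:
                    c[1] += 1
                else:
                    c[2] += 1
        decision = sys._decide(cue)
        if decision.rejected:
            sys_fn += 1
        elif decision.chosen == true_lab:
            sys_tp += 1
        else:
            sys_fp += 1
    reg_stats = [register_metrics(*per_reg[lab]) for lab in sys.registers]
    n_pred = sys_tp + sys_fp
    n_total = sys_tp + sys_fp + sys_fn
    return {
        "register_precision": float(np.mean([m.precision for m in reg_stats])),
        "register_recall": float(np.mean([m.recall for m in reg_stats])),
        "register_accuracy": float(np.mean([m.accuracy for m in reg_stats])),
        "system_precision": 1.0 if n_pred == 0 else sys_tp / n_pred,
        "system_recall": 0.0 if n_total == 0 else sys_tp / n_total,
        "entropy": sys.mean_entropy(),
    }


def run_size_sweep(
    rem_vectors: np.ndarray,
    rem_labels: Sequence[str],
    test_vectors: np.ndarray,
    test_labels: Sequence[str],
    sizes: Iterable[int],
    fills: Iterable[float],
    params: RecognitionParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid over register heights ``m`` and fill fractions of the remembered
    corpus; one metrics row per configuration.  Deterministic given the
    seed (which only drives the fill subsampling order)."""
    rem_vectors = np.asarray(rem_vectors)
    rem_labels = np.asarray(list(rem_labels), dtype=object)
    all_labels = sorted(set(rem_labels) | set(test_labels))
    rows = []
    for m in sizes:
        for fill in fills:
            if not (0.0 < fill <= 1.0):
                raise ValueError(f"fill fraction {fill} outside (0, 1]")
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(rem_vectors))
            n_keep = max(1, int(round(fill * len(rem_vectors))))
            idx = order[:n_keep]
            sys = MemorySystem.build(
                rem_vectors[idx],
                rem_labels[idx],
                all_labels,
                n_levels=m,
                params=params,
                fit_vectors=rem_vectors,
            )
            row = {"m": m, "fill": fill}
            row.update(evaluate_system(sys, test_vectors, test_labels))
            rows.append(row)
    return pd.DataFrame(rows)
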