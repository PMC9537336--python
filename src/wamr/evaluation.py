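"""Phone-string metrics: tokenization, token edit distance, error rate,
per-register precision/recall conventions, and bigram-based simplification.

The phone inventory is the 22-symbol Mexbet basic transcription alphabet for
Mexican Spanish, which contains the multi-character symbols ``tS``, ``n~``
and ``r(``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Mexbet-22 phone inventory (basic transcription level).
MEXBET22: tuple[str, ...] = (
    "a", "e", "i", "o", "u",
    "p", "t", "k", "b", "d", "g",
    "tS", "f", "s", "x", "Z",
    "m", "n", "n~", "l", "r(", "r",
)

# longest-match order: multi-character symbols first
_BY_LENGTH: tuple[str, ...] = tuple(
    sorted(MEXBET22, key=len, reverse=True)
)


class TokenizationError(ValueError):
    """Raised when the input text cannot be segmented into inventory phones."""


@dataclass(frozen=True)
class PhoneString:
    """A sequence of phone tokens, validated against ``inventory`` (pass
    ``inventory=None`` for free-form symbol sets)."""

    tokens: tuple[str, ...]
    inventory: tuple[str, ...] | None = field(
        default=MEXBET22, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.inventory is None:
            return
        bad = [t for t in self.tokens if t not in self.inventory]
        if bad:
            raise ValueError(f"tokens outside the inventory: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __getitem__(self, idx):
        return self.tokens[idx]

    def text(self, sep: str = "") -> str:
        return sep.join(self.tokens)


def tokenize(s: str, sep: str | None = None) -> PhoneString:
    """Segment text into inventory phones by greedy longest match.

    With ``sep=None`` (default) the string is a dense concatenation of
    symbols; pass an explicit separator (e.g. ``" "``) for delimited input.
    Raises :class:`TokenizationError` with the offending position otherwise.
    """
    if sep is not None:
        parts = [p for p in s.split(sep) if p]
        try:
            return PhoneString(tuple(parts))
        except ValueError as exc:
            raise TokenizationError(str(exc)) from exc
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        for sym in _BY_LENGTH:
            if s.startswith(sym, pos):
                tokens.append(sym)
                pos += len(sym)
                break
        else:
            raise TokenizationError(
                f"unmatchable character {s[pos]!r} at position {pos}"
            )
    return PhoneString(tuple(tokens))


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Unit-cost token edit distance by dynamic programming."""
    a = tuple(a)
    b = tuple(b)
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ta in enumerate(a, start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        for j, tb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (ta != tb),  # substitution
            )
        prev = cur
    return int(prev[-1])


def fer(hyp: Sequence[str], ref: Sequence[str]) -> float:
    """Phone error rate as ``d / (d + L)`` where ``d`` is the token edit
    distance and ``L`` the reference length; 0 iff the strings are equal and
    strictly below 1 otherwise."""
    if len(ref) == 0:
        raise ValueError("reference string must be non-empty")
    d = levenshtein(hyp, ref)
    return d / (d + len(ref))


@dataclass(frozen=True)
class RegisterMetrics:
    precision: float
    recall: float
    accuracy: float
    degenerate: bool = False


def register_metrics(tp: int, fp: int, tn: int, fn: int) -> RegisterMetrics:
    """Precision/recall/accuracy with the all-rejected conventions: no
    positive predictions means precision 1, no true positives means recall
    0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    precision = 1.0 if tp + fp == 0 else tp / (tp + fp)
    recall = 0.0 if tp + fn == 0 else tp / (tp + fn)
    accuracy = 0.0 if total == 0 else (tp + tn) / total
    return RegisterMetrics(precision, recall, accuracy, degenerate=total == 0)


@dataclass
class BigramModel:
    """Unigram and bigram-conditional phone probabilities with a mixing
    weight ``w`` for the two-sided acceptance score."""

    unigram: dict[str, float]
    conditional: dict[str, dict[str, float]]  # conditional[a][b] = p(b | a)
    w: float = 0.5
    eps: float = field(default=1e-12, repr=False)

    def p(self, b: str) -> float:
        return self.unigram.get(b, 0.0)

    def p_cond(self, b: str, a: str) -> float:
        return self.conditional.get(a, {}).get(b, 0.0)

    def score(self, b: str, a: str | None, c: str | None) -> float:
        """Acceptance score for phone ``b`` given the previously accepted
        phone ``a`` and the next raw phone ``c``:
        ``w * p(b|a) + (1 - w) * p(c|b) * p(b) / p(c)``.  At the string end
        (no ``c``) only the ``p(b|a)`` term is used."""
        left = self.p_cond(b, a) if a is not None else 1.0
        if c is None:
            return left
        right = self.p_cond(c, b) * self.p(b) / max(self.p(c), self.eps)
        return self.w * left + (1.0 - self.w) * right


def fit_bigram(corpus: Iterable[Sequence[str]], w: float = 0.5) -> BigramModel:
    """Maximum-likelihood unigram and bigram-conditional frequencies from a
    collection of phone strings.  No smoothing beyond an epsilon guard on
    denominators."""
    uni: Counter[str] = Counter()
    bi: Counter[tuple[str, str]] = Counter()
    n_strings = 0
    for s in corpus:
        toks = tuple(s)
        n_strings += 1
        uni.update(toks)
        bi.update(zip(toks, toks[1:]))
    if n_strings == 0:
        raise ValueError("corpus must be non-empty")
    total = sum(uni.values())
    unigram = {t: c / total for t, c in uni.items()}
    firsts: Counter[str] = Counter()
    for (a, _b), c in bi.items():
        firsts[a] += c
    conditional: dict[str, dict[str, float]] = {}
    for (a, b), c in bi.items():
        conditional.setdefault(a, {})[b] = c / firsts[a]
    return BigramModel(unigram=unigram, conditional=conditional, w=w)


def simplify(s: Sequence[str], model: BigramModel) -> PhoneString:
    """Left-to-right bigram filter: keep phone ``b`` iff its two-sided score
    strictly exceeds its unigram probability.

    The first token is kept unconditionally; the conditioning phone ``a`` is
    always the most recently *kept* token while ``c`` is the next token of
    the raw input.
    """
    toks = tuple(s)
    unknown = [t for t in toks if t not in model.unigram]
    if unknown:
        raise ValueError(f"symbols unseen by the model: {sorted(set(unknown))}")
    inventory = s.inventory if isinstance(s, PhoneString) else None
    if not toks:
        return PhoneString((), inventory=inventory)
    kept = [toks[0]]
    for idx in range(1, len(toks)):
        b = toks[idx]
        c = toks[idx + 1] if idx + 1 < len(toks) else None
        if model.score(b, kept[-1], c) > model.p(b):
            kept.append(b)
    return PhoneString(tuple(kept), inventory=inventory)
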