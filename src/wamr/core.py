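"""The weighted associative memory register and its three operations.

A register holds a weighted relation between ``n`` arguments (columns) and
``m`` values (rows).  Cell ``(i, j)`` counts how many stored objects assigned
value ``j`` to argument ``i``; a cell belongs to the relation iff its weight is
non-zero.  Each column induces a probability distribution over values, whose
Shannon entropy averaged over columns measures the indeterminacy of the
register.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

#: Marker for an argument with no assigned value (partial functions).
UNDEFINED: int = -1


class DimensionMismatchError(ValueError):
    """Cue and register do not share the same n x m geometry."""


@dataclass
class FeatureFunction:
    """A (possibly partial) assignment of one of ``n_levels`` values to each
    of ``n_args`` arguments.

    ``assignment[i]`` is the level index of argument ``i`` or
    :data:`UNDEFINED`.  A function with no undefined entries is *total*.
    """

    n_args: int
    n_levels: int
    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.n_args <= 0 or self.n_levels <= 0:
            raise ValueError("n_args and n_levels must be positive")
        if self.assignment.shape != (self.n_args,):
            raise ValueError(
                f"assignment has shape {self.assignment.shape}, "
                f"expected ({self.n_args},)"
            )
        defined = self.assignment != UNDEFINED
        vals = self.assignment[defined]
        if vals.size and (vals.min() < 0 or vals.max() >= self.n_levels):
            raise ValueError("defined levels must lie in [0, n_levels-1]")

    @classmethod
    def total(cls, levels: Sequence[int], n_levels: int) -> "FeatureFunction":
        """Build a total function from an explicit level sequence."""
        levels = np.asarray(levels, dtype=np.int64)
        return cls(n_args=len(levels), n_levels=n_levels, assignment=levels)

    @property
    def defined_mask(self) -> np.ndarray:
        return self.assignment != UNDEFINED

    @property
    def is_total(self) -> bool:
        return bool(np.all(self.defined_mask))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureFunction):
            return NotImplemented
        return (
            self.n_args == other.n_args
            and self.n_levels == other.n_levels
            and bool(np.array_equal(self.assignment, other.assignment))
        )


@dataclass(frozen=True)
class RecognitionParams:
    """Recognition/retrieval control parameters.

    iota
        Cell-sensitivity threshold: a cue argument passes only when the hit
        cell's weight is at least ``iota`` times the column's mean non-zero
        weight.
    kappa
        Cue-strength threshold: the whole cue must satisfy
        ``rho >= kappa * Omega``.
    xi
        Number of arguments allowed to fail the per-argument test.
    sigma
        Standard deviation of the cue-centred retrieval kernel (row units by
        default; see :func:`retrieve`).
    """

    iota: float = 0.0
    kappa: float = 0.0
    xi: int = 0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.iota < 0 or self.kappa < 0 or self.sigma < 0:
            raise ValueError("iota, kappa and sigma must be >= 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


@dataclass
class ColumnStats:
    """Per-column summary: weight sum, support, mean non-zero weight,
    probability vector and entropy (bits)."""

    weight_sum: int
    support: int
    omega: float
    p: np.ndarray
    entropy: float


@dataclass
class RecognitionResult:
    accepted: bool
    per_arg_pass: np.ndarray
    failed_args: int
    rho: float
    omega_bar: float
    entropy: float


@dataclass
class WeightedAMR:
    """An ``n_cols x n_rows`` table of non-negative integer weights."""

    n_cols: int
    n_rows: int
    label: Optional[str] = None
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("n_cols and n_rows must be positive")
        if self.weights is None:
            self.weights = np.zeros((self.n_cols, self.n_rows), dtype=np.int64)
        else:
            self.weights = np.asarray(self.weights, dtype=np.int64)
            if self.weights.shape != (self.n_cols, self.n_rows):
                raise ValueError("weights shape does not match n_cols x n_rows")
            if (self.weights < 0).any():
                raise ValueError("weights must be non-negative")
        self._version = 0

    # -- helpers ---------------------------------------------------------

    def _check_cue(self, cue: FeatureFunction) -> None:
        if cue.n_args != self.n_cols or cue.n_levels != self.n_rows:
            raise DimensionMismatchError(
                f"cue is {cue.n_args}x{cue.n_levels}, "
                f"register is {self.n_cols}x{self.n_rows}"
            )

    def column_stats(self) -> list[ColumnStats]:
        # cached between registrations: recognition sweeps hit this hard
        cached = getattr(self, "_stats_cache", None)
        if cached is not None and cached[0] == self._version:
            return cached[1]
        stats = self._compute_column_stats()
        self._stats_cache = (self._version, stats)
        return stats

    def _compute_column_stats(self) -> list[ColumnStats]:
        stats = []
        for i in range(self.n_cols):
            col = self.weights[i]
            w_sum = int(col.sum())
            support = int(np.count_nonzero(col))
            omega = (w_sum / support) if support else 0.0
            if w_sum > 0:
                p = col / w_sum
                nz = p[p > 0]
                ent = float(-(nz * np.log2(nz)).sum())
            else:
                p = np.zeros(self.n_rows)
                ent = 0.0
            stats.append(ColumnStats(w_sum, support, omega, p, ent))
        return stats

    # -- the three memory operations -------------------------------------

    def register(self, cue: FeatureFunction) -> "WeightedAMR":
        """Additive storage: increment by one every cell addressed by the
        cue's defined arguments.  Returns self for chaining."""
        self._check_cue(cue)
        defined = cue.defined_mask
        cols = np.nonzero(defined)[0]
        self.weights[cols, cue.assignment[cols]] += 1
        self._version += 1
        return self

    def entropy(self) -> tuple[float, list[ColumnStats]]:
        """Average Shannon entropy (bits) of the column distributions,
        with ``0 * log2(0) = 0`` and empty columns contributing 0."""
        stats = self.column_stats()
        e = sum(s.entropy for s in stats) / self.n_cols
        return e, stats

    def basic_entropy(self) -> float:
        """Entropy of the unweighted relation: each non-empty column
        contributes ``log2`` of its number of non-zero cells; empty columns
        contribute 0 (fully determined)."""
        total = 0.0
        for i in range(self.n_cols):
            support = int(np.count_nonzero(self.weights[i]))
            if support > 0:
                total += math.log2(support)
        return total / self.n_cols

    def count_functions(self, registered: int = 0) -> tuple[int, int]:
        """Number of total functions held by the relation and how many of
        them are emergent rather than explicitly registered.

        Returns ``(total, emergent)`` where ``total`` is the product over
        columns of the number of non-zero cells (empty columns contribute a
        factor of 1) and ``emergent = total - registered``.  Exact big-int
        arithmetic: ``total`` equals ``2**(e*n)`` whenever all non-zero
        weights within each column are equal.
        """
        if registered < 0:
            raise ValueError("registered must be >= 0")
        total = 1
        for i in range(self.n_cols):
            support = int(np.count_nonzero(self.weights[i]))
            if support > 0:
                total *= support
        if registered > total:
            raise ValueError(
                f"registered={registered} exceeds the {total} functions "
                "held by the relation"
            )
        return total, total - registered

    def recognize(
        self, cue: FeatureFunction, params: RecognitionParams
    ) -> RecognitionResult:
        """Relaxed material implication test.

        A defined argument ``i`` with cue level ``j`` passes iff
        ``w_ij > 0`` and ``w_ij >= iota * omega_i``; undefined arguments pass
        vacuously.  The cue is accepted iff at most ``xi`` arguments fail and
        the mean cue weight ``rho`` is at least ``kappa`` times the mean of
        the column means ``Omega``.
        """
        self._check_cue(cue)
        stats = self.column_stats()
        omegas = np.array([s.omega for s in stats])
        omega_bar = float(omegas.mean())

        passes = np.ones(self.n_cols, dtype=bool)
        hit = np.zeros(self.n_cols, dtype=np.float64)
        for i in range(self.n_cols):
            j = cue.assignment[i]
            if j == UNDEFINED:
                continue  # empty antecedent: vacuous pass, contributes 0 to rho
            w = self.weights[i, j]
            hit[i] = w
            passes[i] = (w > 0) and (w >= params.iota * omegas[i])
        failed = int((~passes).sum())
        rho = float(hit.sum() / self.n_cols)
        accepted = failed <= params.xi and rho >= params.kappa * omega_bar
        e = sum(s.entropy for s in stats) / self.n_cols
        return RecognitionResult(
            accepted=accepted,
            per_arg_pass=passes,
            failed_args=failed,
            rho=rho,
            omega_bar=omega_bar,
            entropy=e,
        )

    def retrieve(
        self,
        cue: FeatureFunction,
        params: RecognitionParams,
        seed: Union[int, np.random.Generator],
        sigma_units: str = "rows",
    ) -> Optional[FeatureFunction]:
        """Constructive retrieval: sample each output level from the column
        distribution modulated by a discretized normal centred on the cue.

        Returns ``None`` when recognition rejects the cue.  With
        ``sigma = 0`` the output is a photographic copy of the cue at every
        defined argument.  ``sigma_units`` selects whether ``sigma`` is
        measured in rows (default) or as a fraction of the number of rows.
        """
        if sigma_units not in ("rows", "fraction"):
            raise ValueError("sigma_units must be 'rows' or 'fraction'")
        result = self.recognize(cue, params)
        if not result.accepted:
            return None
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        sigma = params.sigma
        if sigma_units == "fraction":
            sigma = sigma * self.n_rows

        stats = self.column_stats()
        out = np.full(self.n_cols, UNDEFINED, dtype=np.int64)
        for i in range(self.n_cols):
            j = cue.assignment[i]
            psi = stats[i].p
            if j == UNDEFINED:
                # partial cue: fall back to the column distribution alone
                if stats[i].weight_sum > 0:
                    out[i] = rng.choice(self.n_rows, p=psi)
                continue
            zeta = _discretized_normal(self.n_rows, center=int(j), sigma=sigma)
            phi = psi * zeta
            mass = phi.sum()
            if mass > 0:
                out[i] = rng.choice(self.n_rows, p=phi / mass)
            elif stats[i].weight_sum > 0:
                # xi-relaxed argument whose cue cell is empty
                out[i] = rng.choice(self.n_rows, p=psi)
            else:
                out[i] = j  # empty column: echo the cue
        return FeatureFunction(self.n_cols, self.n_rows, out)

    # -- dunder sugar -----------------------------------------------------

    def copy(self) -> "WeightedAMR":
        return WeightedAMR(
            self.n_cols, self.n_rows, label=self.label, weights=self.weights.copy()
        )


def _discretized_normal(m: int, center: int, sigma: float) -> np.ndarray:
    """Normal density integrated over unit bins ``[j - 0.5, j + 0.5]``,
    centred at ``center``; a point mass when ``sigma == 0``."""
    if sigma == 0:
        z = np.zeros(m)
        z[center] = 1.0
        return z
    edges = np.arange(m + 1) - 0.5
    cdf = norm.cdf(edges, loc=center, scale=sigma)
    return np.diff(cdf)
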