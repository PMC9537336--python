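"""Min-max linear quantization of real feature vectors to discrete levels.

Per-dimension bounds are fitted from reference data; values are mapped to one
of ``n_levels`` equal-width bins with clipping at the boundaries, and
dequantized back to bin centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wamr.core import FeatureFunction

_EPS_WIDEN = 1e-9


@dataclass
class Quantizer:
    n_dims: int
    n_levels: int
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.float64)
        self.hi = np.asarray(self.hi, dtype=np.float64)
        if self.lo.shape != (self.n_dims,) or self.hi.shape != (self.n_dims,):
            raise ValueError("lo/hi must be per-dimension vectors")
        if not np.all(self.lo < self.hi):
            raise ValueError("lo must be strictly below hi in every dimension")

    @classmethod
    def fit(cls, vectors, n_levels: int) -> "Quantizer":
        """Fit per-dimension min/max bounds; degenerate (constant) dimensions
        are widened by a small epsilon so quantization stays defined."""
        arr = np.asarray(vectors, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("need at least 2 vectors of equal dimension")
        if not np.isfinite(arr).all():
            raise ValueError("reference vectors must be finite")
        lo = arr.min(axis=0)
        hi = arr.max(axis=0)
        degenerate = lo == hi
        widen = np.maximum(np.abs(lo) * _EPS_WIDEN, _EPS_WIDEN)
        lo = np.where(degenerate, lo - widen, lo)
        hi = np.where(degenerate, hi + widen, hi)
        return cls(n_dims=arr.shape[1], n_levels=n_levels, lo=lo, hi=hi)

    @property
    def _width(self) -> np.ndarray:
        return self.hi - self.lo

    def quantize(self, v) -> FeatureFunction:
        """``level_i = floor((v_i - lo_i) / width_i * m)`` clipped to
        ``[0, m - 1]``; out-of-range values clip to the boundary level."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape != (self.n_dims,):
            raise ValueError(f"expected a {self.n_dims}-vector, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("input vector must be finite")
        levels = np.floor((v - self.lo) / self._width * self.n_levels)
        levels = np.clip(levels, 0, self.n_levels - 1).astype(np.int64)
        return FeatureFunction(self.n_dims, self.n_levels, levels)

    def dequantize(self, f: FeatureFunction) -> np.ndarray:
        """Map each level to the center of its bin.  Requires a total
        function."""
        if f.n_args != self.n_dims or f.n_levels != self.n_levels:
            raise ValueError("function geometry does not match the quantizer")
        if not f.is_total:
            raise ValueError("cannot dequantize a partial function")
        return self.lo + (f.assignment + 0.5) * self._width / self.n_levels
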