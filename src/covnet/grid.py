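"""Network-density grids.

Groups are compared at equal edge counts by thresholding each association
matrix over a common grid of network densities (cost levels).  The
conventional grid runs from the minimum density of full connectivity up to
0.50 in steps of 0.02; beyond 0.50 binary covariance graphs become
increasingly random and the comparison loses meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

DEFAULT_STEP = 0.02
DEFAULT_D_MAX = 0.50


@dataclass(frozen=True)
class DensityGrid:
    """An ordered grid of network densities in (0, 1].

    Parameters
    ----------
    d_min, step, d_max : float
        Regular-grid description; ``values`` is derived from these unless
        passed explicitly.
    values : tuple of float
        The actual, strictly increasing density values.
    """

    d_min: float
    step: float = DEFAULT_STEP
    d_max: float = DEFAULT_D_MAX
    values: tuple = field(default=None)

    def __post_init__(self):
        if self.values is None:
            if self.step <= 0:
                raise ConfigurationError(f"density step must be > 0, got {self.step}")
            n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
            vals = np.round(self.d_min + self.step * np.arange(n), 10)
            object.__setattr__(self, "values", tuple(float(v) for v in vals))
        else:
            object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        arr = np.asarray(self.values)
        if arr.size == 0:
            raise ConfigurationError("empty density grid")
        if np.any(arr <= 0) or np.any(arr > 1):
            raise ConfigurationError("densities must lie in (0, 1]")
        if np.any(np.diff(arr) <= 0):
            raise ConfigurationError("density grid must be strictly increasing")

    @classmethod
    def regular(cls, d_min: float = DEFAULT_STEP, step: float = DEFAULT_STEP,
                d_max: float = DEFAULT_D_MAX) -> "DensityGrid":
        return cls(d_min=d_min, step=step, d_max=d_max)

    def truncate_from(self, d_min: float) -> "DensityGrid":
        """Drop grid points below ``d_min`` (used once D_min is known)."""
        kept = tuple(v for v in self.values if v >= d_min - 1e-12)
        if not kept:
            raise ConfigurationError(
                f"truncating at {d_min} leaves no grid points (grid max {self.values[-1]})")
        return DensityGrid(d_min=kept[0], step=self.step, d_max=self.d_max, values=kept)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)
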