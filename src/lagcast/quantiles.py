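"""Probabilistic estimates as 23-level quantile sets.

Every hindcast and forecast is represented by its quantiles at the 23
levels {0.01, 0.025, 0.05, 0.1, 0.15, ..., 0.95, 0.975, 0.99} (step 0.05
between 0.1 and 0.95); the 0.5-level entry doubles as the point estimate.
Mortality rates cannot be negative, so quantiles are clipped at zero, and
within each target month the values are sorted to enforce monotonicity
across levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LEVELS = np.concatenate(
    ([0.01, 0.025, 0.05], np.round(np.arange(0.10, 0.951, 0.05), 2), [0.975, 0.99])
)
assert len(LEVELS) == 23

_MEDIAN_IDX = int(np.where(LEVELS == 0.5)[0][0])


@dataclass(frozen=True)
class QuantileForecast:
    """Quantile estimates for a contiguous span of target months.

    Attributes
    ----------
    target_months
        Ordered month indices the estimates refer to.
    values
        Array of shape (n_target_months, 23): quantile values per month,
        non-decreasing across levels, non-negative.
    horizon_kind
        ``"hindcast"`` (gap months m-l .. m) or ``"forecast"`` (m+1 .. m+h).
    """

    target_months: np.ndarray
    values: np.ndarray
    horizon_kind: str = "forecast"

    def __post_init__(self):
        object.__setattr__(self, "target_months", np.asarray(self.target_months, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.horizon_kind not in ("hindcast", "forecast"):
            raise ValueError(f"horizon_kind must be hindcast|forecast, got {self.horizon_kind!r}")
        if self.values.shape != (len(self.target_months), len(LEVELS)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.target_months)}, {len(LEVELS)})"
            )
        if np.any(np.diff(self.values, axis=1) < 0):
            raise ValueError("quantile values must be non-decreasing across levels")
        if np.any(self.values < 0):
            raise ValueError("quantile values must be non-negative")

    def __len__(self) -> int:
        return len(self.target_months)

    @property
    def point_estimate(self) -> np.ndarray:
        """Median (0.5-level) estimate per target month."""
        return self.values[:, _MEDIAN_IDX]

    @classmethod
    def from_paths(cls, paths, target_months, horizon_kind: str = "forecast") -> "QuantileForecast":
        """Empirical quantiles of simulated sample paths.

        Parameters
        ----------
        paths
            Array of shape (n_paths, n_target_months).
        """
        paths = np.asarray(paths, dtype=float)
        q = np.quantile(paths, LEVELS, axis=0).T  # (months, levels)
        q = np.sort(q, axis=1)
        q = np.clip(q, 0.0, None)
        return cls(target_months=target_months, values=q, horizon_kind=horizon_kind)

    @classmethod
    def point_mass(cls, values, target_months, horizon_kind: str = "forecast") -> "QuantileForecast":
        """Degenerate forecast with all 23 levels at the given trajectory."""
        v = np.clip(np.asarray(values, dtype=float), 0.0, None)
        return cls(
            target_months=target_months,
            values=np.repeat(v[:, None], len(LEVELS), axis=1),
            horizon_kind=horizon_kind,
        )
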