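"""Temperature-field container shared by the Laplace and finite-difference paths."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["TemperatureField"]


@dataclass(frozen=True)
class TemperatureField:
    """Dimensionless temperatures on a (y, t) grid with provenance metadata.

    ``values[i, j]`` is theta at ``y_grid[i]``, ``t_grid[j]``. ``metadata``
    records the producing method and its settings so every table written to
    disk can be traced back to a run configuration.
    """

    values: np.ndarray
    y_grid: np.ndarray
    t_grid: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        y = np.asarray(self.y_grid, dtype=float)
        t = np.asarray(self.t_grid, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "y_grid", y)
        object.__setattr__(self, "t_grid", t)
        if values.shape != (y.size, t.size):
            raise ValueError(
                f"values shape {values.shape} != (len(y), len(t)) = "
                f"({y.size}, {t.size})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("temperature field contains non-finite values")

    def at(self, y: float, t: float) -> float:
        """Value at an exact grid node (no interpolation)."""
        i = int(np.argmin(np.abs(self.y_grid - y)))
        j = int(np.argmin(np.abs(self.t_grid - t)))
        if abs(self.y_grid[i] - y) > 1e-12 or abs(self.t_grid[j] - t) > 1e-12:
            raise KeyError(f"(y={y}, t={t}) is not a grid node")
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format records (y, t, theta)."""
        yy, tt = np.meshgrid(self.y_grid, self.t_grid, indexing="ij")
        return pd.DataFrame(
            {"y": yy.ravel(), "t": tt.ravel(), "theta": self.values.ravel()}
        )
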