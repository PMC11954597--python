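"""Uniformly sampled time series container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued trace.

    Parameters
    ----------
    t0 : float
        Start time, in the units declared by ``time_unit``.
    dt : float
        Sampling interval (> 0), same units as ``t0``.
    values : numpy.ndarray
        Sample values; at least two samples, all finite.
    label : str
        Free-form channel / compartment identifier.
    time_unit : str
        Either ``"min"`` or ``"s"``.
    """

    t0: float
    dt: float
    values: np.ndarray
    label: str = ""
    time_unit: str = "min"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.time_unit not in ("min", "s"):
            raise ValueError(f"time_unit must be 'min' or 's', got {self.time_unit!r}")

    @property
    def t(self) -> np.ndarray:
        """Time grid of the samples."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """Copy of this series carrying new values on the same grid."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if label is not None:
            out.label = label
        return out

    def same_grid(self, other: "TimeSeries", rtol: float = 1e-9) -> bool:
        return (
            self.values.size == other.values.size
            and self.time_unit == other.time_unit
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0 - other.t0) <= rtol * max(self.dt, 1.0)
        )

    def require_same_grid(self, other: "TimeSeries") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"time grids differ: ({self.t0}, {self.dt}, n={self.values.size}, "
                f"{self.time_unit}) vs ({other.t0}, {other.dt}, n={other.values.size}, "
                f"{other.time_unit})"
            )
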