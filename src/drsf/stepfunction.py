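"""Right-continuous step functions on an event-time grid.

A :class:`StepFunction` is the prediction currency of every model in the
package: a cumulative hazard H(t) (or any nondecreasing curve) defined by
its jump grid.  It evaluates to 0 before the first grid point and to the
last value after the last grid point.
"""

from __future__ import annotations

import numpy as np


class StepFunction:
    """Right-continuous step function ``t -> values[grid <= t]``.

    Parameters
    ----------
    grid : array-like of float
        Strictly increasing knot locations (event times, in days).
    values : array-like of float
        Function value at and after each knot.  For a cumulative hazard
        the values are nonnegative and nondecreasing with H(0) = 0
        implied by the evaluation rule.
    """

    __slots__ = ("grid", "values")

    def __init__(self, grid, values):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or values.ndim != 1:
            raise ValueError("grid and values must be one-dimensional")
        if grid.shape != values.shape:
            raise ValueError("grid and values must have equal length")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        self.grid = grid
        self.values = values

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.grid, t, side="right")
        padded = np.concatenate(([0.0], self.values))
        out = padded[idx]
        return out if out.ndim else float(out)

    def __len__(self) -> int:
        return int(self.grid.size)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StepFunction)
            and self.grid.shape == other.grid.shape
            and bool(np.all(self.grid == other.grid))
            and bool(np.all(self.values == other.values))
        )

    def __repr__(self) -> str:
        return f"StepFunction(n_knots={self.grid.size})"

    def to_csv(self, path) -> None:
        """Write the knots as a two-column CSV (time, value)."""
        arr = np.column_stack([self.grid, self.values])
        np.savetxt(path, arr, delimiter=",", header="time,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "StepFunction":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if arr.size == 0:
            return cls([], [])
        return cls(arr[:, 0], arr[:, 1])
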