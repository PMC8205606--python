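"""Wavelength grids.

The instrument samples reflectance on a uniform grid; the acquisition used
throughout this package covers 900-2500 nm at 3.125 nm spacing, which under
the half-open convention [start, end) gives exactly 512 points.  The
half-open convention is part of the format contract: the last implied
wavelength is ``end_nm - step_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridDefinitionError

__all__ = ["WavelengthGrid", "make_grid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid: ``start_nm + i * step_nm`` for i in [0, n_points)."""

    start_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise GridDefinitionError(f"grid needs >= 2 points, got {self.n_points}")
        if self.step_nm <= 0:
            raise GridDefinitionError(f"step must be positive, got {self.step_nm}")

    @property
    def end_nm(self) -> float:
        """Half-open upper edge: one step beyond the last wavelength."""
        return self.start_nm + self.n_points * self.step_nm

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, wl, rtol: float = 1e-6) -> "WavelengthGrid":
        """Recover (start, step, n) from an explicit wavelength vector.

        Raises :class:`GridDefinitionError` if spacing is non-uniform or
        non-increasing beyond ``rtol`` of the median step.
        """
        wl = np.asarray(wl, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise GridDefinitionError("need a 1-D vector of >= 2 wavelengths")
        steps = np.diff(wl)
        step = float(np.median(steps))
        if step <= 0:
            raise GridDefinitionError("wavelengths must be strictly increasing")
        bad = np.nonzero(np.abs(steps - step) > rtol * abs(step))[0]
        if bad.size:
            i = int(bad[0])
            raise GridDefinitionError(
                f"non-uniform spacing at column {i + 1}: step {steps[i]:g} != {step:g}"
            )
        return cls(start_nm=float(wl[0]), step_nm=step, n_points=int(wl.size))


def make_grid(start_nm: float, end_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a half-open [start, end) grid; the range must divide evenly.

    ``make_grid(900, 2500, 3.125)`` yields the instrument's 512-point grid.
    """
    if end_nm <= start_nm:
        raise GridDefinitionError(f"end {end_nm} must exceed start {start_nm}")
    if step_nm <= 0:
        raise GridDefinitionError(f"step must be positive, got {step_nm}")
    span = end_nm - start_nm
    n_float = span / step_nm
    n = int(round(n_float))
    remainder = span - n * step_nm
    if abs(remainder) > 1e-9:
        raise GridDefinitionError(
            f"range {span} nm is not a multiple of step {step_nm} nm "
            f"(remainder {remainder:g} nm)"
        )
    return WavelengthGrid(start_nm=float(start_nm), step_nm=float(step_nm), n_points=n)


#: The acquisition grid used by the study design: 512 points, 900-2500 nm.
DEFAULT_GRID = make_grid(900.0, 2500.0, 3.125)
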