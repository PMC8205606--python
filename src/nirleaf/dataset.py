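"""In-memory containers for labeled replicate spectra.

A *sample* is one leaf, measured at several spots (six in the study design);
the working spectrum of a leaf is the per-wavelength arithmetic mean of its
spot spectra, taken on raw reflectance before any preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SpectraParseError
from .grid import WavelengthGrid

__all__ = [
    "MATURITY_LEVELS",
    "POSITIONS",
    "SpectrumRecord",
    "SpectraSet",
    "average_replicates",
]

#: Ordinal harvest-readiness grades, in increasing ripeness order. The
#: integer class index used by every classifier is the position in this tuple.
MATURITY_LEVELS: tuple[str, ...] = ("unripe", "mature", "ripe", "mellow", "overmature")

#: Stalk position of the leaf; each position gets its own discriminant model.
POSITIONS: tuple[str, ...] = ("upper", "middle", "lower")

MATURITY_INDEX = {m: i for i, m in enumerate(MATURITY_LEVELS)}
POSITION_INDEX = {p: i for i, p in enumerate(POSITIONS)}


def average_replicates(spot_spectra: np.ndarray) -> np.ndarray:
    """Per-wavelength arithmetic mean of an ``n_spots x n_points`` matrix."""
    spot_spectra = np.asarray(spot_spectra, dtype=float)
    if spot_spectra.ndim != 2 or spot_spectra.shape[0] < 1:
        raise ParameterError(
            f"spot spectra must be a non-empty 2-D matrix, got shape {spot_spectra.shape}"
        )
    return spot_spectra.mean(axis=0)


@dataclass
class SpectrumRecord:
    """One leaf: replicate spot spectra plus position and maturity labels."""

    sample_id: str
    position: str
    maturity: str
    spot_spectra: np.ndarray  # n_spots x n_points

    def __post_init__(self) -> None:
        if self.position not in POSITION_INDEX:
            raise SpectraParseError(
                f"unknown position token {self.position!r} "
                f"(expected one of {', '.join(POSITIONS)})"
            )
        if self.maturity not in MATURITY_INDEX:
            raise SpectraParseError(
                f"unknown maturity token {self.maturity!r} "
                f"(expected one of {', '.join(MATURITY_LEVELS)})"
            )
        self.spot_spectra = np.atleast_2d(np.asarray(self.spot_spectra, dtype=float))

    @property
    def n_spots(self) -> int:
        return self.spot_spectra.shape[0]

    @property
    def mean_spectrum(self) -> np.ndarray:
        return average_replicates(self.spot_spectra)

    @property
    def label_index(self) -> int:
        return MATURITY_INDEX[self.maturity]


@dataclass
class SpectraSet:
    """A wavelength grid plus a list of labeled records conforming to it."""

    grid: WavelengthGrid
    records: list[SpectrumRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.spot_spectra.shape[1] != self.grid.n_points:
                raise SpectraParseError(
                    f"record {rec.sample_id!r} has {rec.spot_spectra.shape[1]} points, "
                    f"grid has {self.grid.n_points}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def mean_spectra(self) -> np.ndarray:
        """n_records x n_points matrix of replicate-averaged spectra."""
        return np.vstack([rec.mean_spectrum for rec in self.records])

    def labels(self) -> np.ndarray:
        """Integer maturity classes in MATURITY_LEVELS order."""
        return np.array([rec.label_index for rec in self.records], dtype=int)

    def maturity_tokens(self) -> list[str]:
        return [rec.maturity for rec in self.records]

    def subset(self, indices) -> "SpectraSet":
        return SpectraSet(self.grid, [self.records[i] for i in indices])
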