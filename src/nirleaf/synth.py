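"""Synthetic labeled NIR spectra.

The study's field data are embargoed, so every test and example here runs
on simulated spectra that carry the same structure the pipeline assumes: a
smooth class-dependent reflectance curve built from Gaussian absorption-like
bands, corrupted per spot scan by the classic scatter model

    observed = b * pure + a + c * wavelength + noise,

with multiplicative scatter ``b``, additive offset ``a``, linear baseline
slope ``c`` and i.i.d. point noise.  Maturity levels differ by per-band
center shifts and amplitude gains; each leaf yields several replicate spot
spectra (six by default, matching the acquisition protocol).  The scatter
terms are exactly the distortions SNV, MSC and derivative pretreatments are
designed to invert, which makes the preprocessing comparisons directional
rather than arbitrary.  No claim of chemical realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MATURITY_LEVELS, POSITIONS, SpectraSet, SpectrumRecord
from .errors import ParameterError
from .grid import DEFAULT_GRID, WavelengthGrid

__all__ = ["BandSpec", "SynthConfig", "pure_spectrum", "simulate_dataset", "easy_benchmark"]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band with per-maturity-level center drift and gain."""

    center_nm: float
    width_nm: float
    base_amplitude: float = 1.0
    maturity_shift_nm: tuple[float, ...] = (0.0,) * 5
    maturity_gain: tuple[float, ...] = (1.0,) * 5

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ParameterError(f"band width must be positive, got {self.width_nm}")
        if len(self.maturity_shift_nm) != len(MATURITY_LEVELS):
            raise ParameterError("maturity_shift_nm needs one entry per maturity level")
        if len(self.maturity_gain) != len(MATURITY_LEVELS):
            raise ParameterError("maturity_gain needs one entry per maturity level")


def _default_bands() -> dict[str, list[BandSpec]]:
    """A small band library per leaf position.

    Band centers sit on typical NIR overtone regions (water ~970/1450/1940,
    C-H ~1200/1700/2300 nm); ripening is encoded as modest center drift plus
    amplitude change, different in detail per position so each position is
    its own classification problem.
    """
    def ramp(lo, hi):
        return tuple(np.linspace(lo, hi, len(MATURITY_LEVELS)))

    common = [
        BandSpec(970, 60, 0.8, ramp(0, 12), ramp(1.0, 0.75)),
        BandSpec(1200, 90, 0.6, ramp(0, -10), ramp(0.9, 1.15)),
        BandSpec(1450, 80, 1.0, ramp(0, 15), ramp(1.1, 0.8)),
        BandSpec(1720, 100, 0.5, ramp(0, 8), ramp(0.8, 1.1)),
        BandSpec(1940, 90, 1.1, ramp(0, 18), ramp(1.2, 0.85)),
        BandSpec(2300, 110, 0.6, ramp(0, -12), ramp(0.85, 1.1)),
    ]
    return {
        "upper": common,
        "middle": [BandSpec(b.center_nm + 15, b.width_nm, b.base_amplitude,
                            b.maturity_shift_nm, b.maturity_gain) for b in common],
        "lower": [BandSpec(b.center_nm - 15, b.width_nm, b.base_amplitude,
                           b.maturity_shift_nm, b.maturity_gain) for b in common],
    }


@dataclass
class SynthConfig:
    """Generator settings; identical config + seed gives an identical dataset."""

    grid: WavelengthGrid = field(default_factory=lambda: DEFAULT_GRID)
    bands: dict[str, list[BandSpec]] = field(default_factory=_default_bands)
    positions: tuple[str, ...] = POSITIONS
    n_per_class: int = 20
    n_spots: int = 6
    scatter_mult_range: tuple[float, float] = (0.8, 1.2)
    scatter_add_sd: float = 0.05
    baseline_slope_sd: float = 0.0001
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.n_spots < 1:
            raise ParameterError(f"n_spots must be >= 1, got {self.n_spots}")
        lo, hi = self.scatter_mult_range
        if not (0 < lo <= hi):
            raise ParameterError(f"bad scatter_mult_range {self.scatter_mult_range}")


def pure_spectrum(config: SynthConfig, position: str, maturity: str) -> np.ndarray:
    """Noise-free class spectrum: sum of shifted, gained Gaussian bands."""
    if position not in config.bands:
        raise ParameterError(f"no band library for position {position!r}")
    level = MATURITY_LEVELS.index(maturity)
    wl = config.grid.wavelengths()
    out = np.zeros_like(wl)
    for band in config.bands[position]:
        center = band.center_nm + band.maturity_shift_nm[level]
        amp = band.base_amplitude * band.maturity_gain[level]
        out += amp * np.exp(-0.5 * ((wl - center) / band.width_nm) ** 2)
    return out


def simulate_dataset(config: SynthConfig) -> SpectraSet:
    """Generate exactly ``n_per_class`` leaves per (position, maturity).

    Per spot scan, one multiplicative factor ``b ~ U(scatter_mult_range)``,
    one offset ``a ~ N(0, scatter_add_sd)`` and one baseline slope
    ``c ~ N(0, baseline_slope_sd)`` distort the pure spectrum; point noise
    is i.i.d. ``N(0, noise_sd)``.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.grid.wavelengths()
    wl_centered = wl - wl.mean()  # keeps slope and offset effects separable
    records: list[SpectrumRecord] = []
    counter = 0
    for position in config.positions:
        pure = {m: pure_spectrum(config, position, m) for m in MATURITY_LEVELS}
        for maturity in MATURITY_LEVELS:
            for _ in range(config.n_per_class):
                b = rng.uniform(*config.scatter_mult_range, size=(config.n_spots, 1))
                a = rng.normal(0.0, config.scatter_add_sd, size=(config.n_spots, 1))
                c = rng.normal(0.0, config.baseline_slope_sd, size=(config.n_spots, 1))
                eps = rng.normal(0.0, config.noise_sd,
                                 size=(config.n_spots, config.grid.n_points))
                spots = b * pure[maturity] + a + c * wl_centered + eps
                records.append(SpectrumRecord(
                    sample_id=f"{position}-{maturity}-{counter:05d}",
                    position=position,
                    maturity=maturity,
                    spot_spectra=spots,
                ))
                counter += 1
    return SpectraSet(grid=config.grid, records=records)


def easy_benchmark(seed: int = 0, position: str = "upper",
                   n_per_class: int = 56) -> SpectraSet:
    """Canonical well-separated 5-class benchmark for one leaf position.

    Sized like one position dataset of the study design scaled down about
    four-fold (56 x 5 = 280 leaves), with large maturity shifts and high
    signal-to-noise so that every classifier in the models module should
    discriminate it; used by the acceptance tests.
    """
    base = _default_bands()[position]
    strong = [
        BandSpec(
            b.center_nm, b.width_nm, b.base_amplitude,
            tuple(3.0 * s for s in b.maturity_shift_nm),
            tuple(1.0 + 2.5 * (g - 1.0) for g in b.maturity_gain),
        )
        for b in base
    ]
    config = SynthConfig(
        bands={position: strong},
        positions=(position,),
        n_per_class=n_per_class,
        noise_sd=0.002,
        scatter_add_sd=0.05,
        baseline_slope_sd=5e-6,
        seed=seed,
    )
    return simulate_dataset(config)
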