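"""CSV interchange for spectra sets.

Wide layout, one row per spot scan::

    sample_id,position,maturity,900,903.125,...

The wavelength header must be strictly increasing with uniform spacing;
rows sharing a ``sample_id`` are the replicate spots of one leaf and must
agree in position and maturity.  Missing values are not permitted — the
instrument emits dense arrays.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpectraSet, SpectrumRecord
from .errors import GridDefinitionError, SpectraParseError
from .grid import WavelengthGrid

__all__ = ["read_spectra_csv", "write_spectra_csv"]

_META_COLS = ("sample_id", "position", "maturity")


def _format_wavelength(wl: float) -> str:
    """Print with <= 4 decimals, trimming trailing zeros."""
    s = f"{wl:.4f}".rstrip("0").rstrip(".")
    return s


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write one row per spot scan in the wide CSV dialect."""
    wl_cols = [_format_wavelength(w) for w in spectra.grid.wavelengths()]
    rows = []
    meta = []
    for rec in spectra.records:
        for spot in rec.spot_spectra:
            meta.append((rec.sample_id, rec.position, rec.maturity))
            rows.append(spot)
    frame = pd.DataFrame(np.vstack(rows), columns=wl_cols)
    for i, name in enumerate(_META_COLS):
        frame.insert(i, name, [m[i] for m in meta])
    frame.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path) -> SpectraSet:
    """Read the wide CSV dialect back into a :class:`SpectraSet`.

    Round-trips :func:`write_spectra_csv` to 1e-12 in values and exactly in
    labels.  Raises :class:`SpectraParseError` with a row/column reference
    for ragged rows, unknown label tokens, or a non-uniform header.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={c: str for c in _META_COLS})
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraParseError(f"{path.name}: {exc}") from exc
    for name in _META_COLS:
        if name not in frame.columns:
            raise SpectraParseError(f"{path.name}: missing metadata column {name!r}")
    wl_names = [c for c in frame.columns if c not in _META_COLS]
    if len(wl_names) < 2:
        raise SpectraParseError(f"{path.name}: fewer than 2 wavelength columns")
    try:
        wl = np.array([float(c) for c in wl_names])
    except ValueError as exc:
        raise SpectraParseError(f"{path.name}: non-numeric wavelength column: {exc}") from exc
    try:
        grid = WavelengthGrid.from_wavelengths(wl)
    except GridDefinitionError as exc:
        raise SpectraParseError(f"{path.name}: bad wavelength header: {exc}") from exc

    values = frame[wl_names].to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise SpectraParseError(
            f"{path.name}: missing value at data row {r + 1}, column {wl_names[c]!r}"
        )

    records: list[SpectrumRecord] = []
    # groupby(sort=False) preserves first-appearance order of sample ids
    for sample_id, group in frame.groupby("sample_id", sort=False):
        positions = group["position"].unique()
        maturities = group["maturity"].unique()
        if len(positions) != 1 or len(maturities) != 1:
            raise SpectraParseError(
                f"{path.name}: sample {sample_id!r} has inconsistent labels across spots"
            )
        try:
            rec = SpectrumRecord(
                sample_id=str(sample_id),
                position=str(positions[0]),
                maturity=str(maturities[0]),
                spot_spectra=group[wl_names].to_numpy(dtype=float),
            )
        except SpectraParseError as exc:
            row = int(group.index[0]) + 1
            raise SpectraParseError(f"{path.name}: data row {row}: {exc}") from exc
        records.append(rec)
    if not records:
        raise SpectraParseError(f"{path.name}: no data rows")
    return SpectraSet(grid=grid, records=records)
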