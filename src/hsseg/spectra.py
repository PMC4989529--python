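"""Reference emissivity spectra.

A :class:`ReferenceSpectrum` holds the expected per-band emissivity values
L_PAT(i) of a target material together with the wavelength axis.  Spectra
are exchanged as two-column CSV files (``wavelength_um,value``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, RangeError

__all__ = ["ReferenceSpectrum", "read_spectrum_csv", "write_spectrum_csv"]


@dataclass(frozen=True)
class ReferenceSpectrum:
    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        w = np.asarray(self.wavelengths, dtype=np.float64)
        if v.ndim != 1 or w.ndim != 1 or v.shape != w.shape:
            raise DimensionError(
                f"values and wavelengths must be equal-length 1D arrays, "
                f"got {v.shape} and {w.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise RangeError("reference spectrum values must be finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "wavelengths", w)

    def __len__(self) -> int:
        return self.values.size

    def require_bands(self, bands: int) -> None:
        if len(self) != bands:
            raise DimensionError(
                f"reference spectrum has {len(self)} bands, cube has {bands}"
            )


def write_spectrum_csv(spectrum: ReferenceSpectrum, path) -> None:
    data = np.column_stack([spectrum.wavelengths, spectrum.values])
    np.savetxt(path, data, delimiter=",", header="wavelength_um,value", comments="")


def read_spectrum_csv(path) -> ReferenceSpectrum:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return ReferenceSpectrum(values=data[:, 1], wavelengths=data[:, 0])
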