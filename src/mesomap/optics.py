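"""Optical model for multi-wavelength hemoglobin spectroscopy.

Bundles a hemoglobin extinction compilation (see ``data/hb_extinction.csv``)
and per-wavelength differential pathlength factors, and exposes the
``OpticsModel`` consumed by both the forward reflectance model and the
Beer-Lambert inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

DEFAULT_WAVELENGTHS = (478.0, 588.0, 610.0, 625.0)


def _load_csv(name: str):
    import pandas as pd

    with resources.files("mesomap.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def extinction_table(wavelengths) -> np.ndarray:
    """Molar extinction coefficients at the requested wavelengths.

    Linear interpolation of the bundled HbO2/HbR compilation. Returns an
    (n_wavelengths, 2) array, columns (eps_HbO, eps_HbR), in 1/(M*cm).

    Raises ``ValueError`` for wavelengths outside the tabulated range.
    """
    tab = _load_csv("hb_extinction.csv")
    grid = tab["wavelength_nm"]
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    if wl.min() < grid.min() or wl.max() > grid.max():
        raise ValueError(
            f"wavelengths must lie within [{grid.min():g}, {grid.max():g}] nm")
    eps_hbo = np.interp(wl, grid, tab["eps_hbo2"])
    eps_hbr = np.interp(wl, grid, tab["eps_hbr"])
    return np.column_stack([eps_hbo, eps_hbr])


def default_pathlengths(wavelengths) -> np.ndarray:
    """Bundled differential pathlength factors (cm) at the given wavelengths."""
    tab = _load_csv("pathlengths.csv")
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    return np.interp(wl, tab["wavelength_nm"], tab["pathlength_cm"])


@dataclass(frozen=True)
class OpticsModel:
    """Wavelengths, extinction matrix and pathlengths for spectroscopy.

    extinction : (n_wavelengths, 2) array, columns (HbO, HbR), 1/(M*cm)
    pathlength : (n_wavelengths,) effective pathlength per wavelength, cm
    baseline_hbo / baseline_hbr : resting concentrations (M); informational
        only — the pipeline works exclusively with concentration changes.
    """

    wavelengths: tuple
    extinction: np.ndarray
    pathlength: np.ndarray
    baseline_hbo: float = 60e-6
    baseline_hbr: float = 40e-6

    def __post_init__(self):
        ext = np.asarray(self.extinction, dtype=float)
        pl = np.asarray(self.pathlength, dtype=float)
        if ext.shape != (len(self.wavelengths), 2):
            raise ValueError("extinction must be (n_wavelengths, 2)")
        if np.any(ext < 0):
            raise ValueError("extinction coefficients must be non-negative")
        if np.any(pl <= 0):
            raise ValueError("pathlengths must be positive")
        if len(self.wavelengths) < 2:
            raise ValueError("at least 2 wavelengths are required")
        object.__setattr__(self, "extinction", ext)
        object.__setattr__(self, "pathlength", pl)

    @property
    def design_matrix(self) -> np.ndarray:
        """Pathlength-weighted extinction matrix E*L, (n_wavelengths, 2)."""
        return self.extinction * self.pathlength[:, None]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.design_matrix))


def default_optics(wavelengths=DEFAULT_WAVELENGTHS) -> OpticsModel:
    """OpticsModel for the 4-LED system (478, 588, 610, 625 nm)."""
    wl = tuple(float(w) for w in wavelengths)
    return OpticsModel(wavelengths=wl,
                       extinction=extinction_table(wl),
                       pathlength=default_pathlengths(wl))
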