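"""Hemoglobin optical-absorption model shared by the simulator and the unmixer.

Two-wavelength photoacoustic oximetry works because oxy- and deoxyhemoglobin
have distinct molar extinction spectra: at 532 nm the two species absorb
comparably, while at 558 nm deoxyhemoglobin absorbs substantially more.
A :class:`ChromophoreTable` holds the tabulated extinction spectra
``eps_HbO2(lambda)`` and ``eps_Hb(lambda)`` (cm^-1 M^-1) on a strictly
increasing wavelength grid and interpolates them piecewise-linearly.
Concentrations are treated as *relative* (arbitrary units) throughout:
oxygen saturation SO2 = C_HbO2 / (C_HbO2 + C_Hb) is invariant to the common
scale, so absolute molarity is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np

LN10 = float(np.log(10.0))

#: Species labels accepted by :meth:`ChromophoreTable.extinction`.
SPECIES = ("HbO2", "Hb")

_DEFAULT_RESOURCE = "hb_extinction_synthetic.csv"
_DEFAULT_SOURCE_ID = "synthetic-hb-compilation-v1"


class WavelengthRangeError(ValueError):
    """Requested wavelength lies outside the table's grid span."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Tabulated molar extinction spectra of HbO2 and Hb.

    Parameters
    ----------
    wavelength_nm
        Strictly increasing wavelength grid (nm). Must span at least
        [450, 1000] nm and bracket 532, 558 and 830 nm.
    eps_hbo2, eps_hb
        Molar extinction coefficients (cm^-1 M^-1) per grid point,
        strictly positive and finite.
    source_id
        Provenance string identifying the tabulation.
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    source_id: str = _DEFAULT_SOURCE_ID

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        e_o = np.asarray(self.eps_hbo2, dtype=float)
        e_d = np.asarray(self.eps_hb, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not (e_o.shape == wl.shape and e_d.shape == wl.shape):
            raise ValueError("extinction arrays must match the wavelength grid shape")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(e_o)) and np.all(np.isfinite(e_d))):
            raise ValueError("extinction values must be finite")
        if not (np.all(e_o > 0) and np.all(e_d > 0)):
            raise ValueError("extinction values must be strictly positive")
        if wl[0] > 450.0 or wl[-1] < 1000.0:
            raise ValueError(
                f"table must span at least [450, 1000] nm, got "
                f"[{wl[0]:g}, {wl[-1]:g}] nm"
            )
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "eps_hbo2", e_o)
        object.__setattr__(self, "eps_hb", e_d)
        # physical basis of the 532/558 pair: Hb dominates at 558 nm
        if not self.extinction(558.0, "Hb") > self.extinction(558.0, "HbO2"):
            raise ValueError("table violates eps_Hb(558) > eps_HbO2(558)")

    # ------------------------------------------------------------------ span
    @property
    def span(self) -> tuple[float, float]:
        """(min, max) wavelength of the grid in nm."""
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def _check_span(self, wavelength_nm: np.ndarray) -> None:
        lo, hi = self.span
        w = np.asarray(wavelength_nm, dtype=float)
        if np.any(w < lo) or np.any(w > hi):
            raise WavelengthRangeError(
                f"wavelength outside table span [{lo:g}, {hi:g}] nm"
            )

    # ----------------------------------------------------------- interpolate
    def extinction(
        self, wavelength_nm: Union[float, np.ndarray], species: str
    ) -> Union[float, np.ndarray]:
        """Piecewise-linear molar extinction at ``wavelength_nm`` (cm^-1 M^-1).

        Exact table values are returned at grid points; the table is never
        extrapolated (out-of-span queries raise
        :class:`WavelengthRangeError`).
        """
        if species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
        self._check_span(wavelength_nm)
        eps = self.eps_hbo2 if species == "HbO2" else self.eps_hb
        out = np.interp(np.asarray(wavelength_nm, dtype=float), self.wavelength_nm, eps)
        return float(out) if np.isscalar(wavelength_nm) else out

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_csv(cls, path: Union[str, Path], source_id: str | None = None) -> "ChromophoreTable":
        """Load a table from a CSV with columns wavelength_nm, eps_hbo2, eps_hb."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        arr = df.to_numpy(dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2],
                   source_id=source_id or str(path))

    @classmethod
    def default(cls) -> "ChromophoreTable":
        """The packaged synthetic hemoglobin compilation (see module docs)."""
        ref = resources.files("pars_oxi._data").joinpath(_DEFAULT_RESOURCE)
        with resources.as_file(ref) as path:
            table = cls.from_csv(path, source_id=_DEFAULT_SOURCE_ID)
        return table


def extinction_at(table: ChromophoreTable, wavelength_nm, species: str):
    """Functional alias for :meth:`ChromophoreTable.extinction`."""
    return table.extinction(wavelength_nm, species)


@dataclass(frozen=True)
class BloodOpticalState:
    """Relative oxy-/deoxyhemoglobin concentrations of a blood volume.

    Concentrations are in arbitrary (relative) units, both non-negative.
    ``so2`` is derived: C_HbO2 / (C_HbO2 + C_Hb).
    """

    c_hbo2: float
    c_hb: float

    def __post_init__(self) -> None:
        if self.c_hbo2 < 0 or self.c_hb < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def so2(self) -> float:
        total = self.c_hbo2 + self.c_hb
        if total <= 0:
            raise ValueError("SO2 undefined for zero total hemoglobin")
        return self.c_hbo2 / total

    @classmethod
    def from_so2(cls, so2: float, total: float = 1.0) -> "BloodOpticalState":
        if not 0.0 <= so2 <= 1.0:
            raise ValueError("so2 must be in [0, 1]")
        if total <= 0:
            raise ValueError("total concentration must be positive")
        return cls(c_hbo2=so2 * total, c_hb=(1.0 - so2) * total)


def absorption_coefficient(
    state: BloodOpticalState, table: ChromophoreTable, wavelength_nm
):
    """Blood absorption coefficient mu_a (cm^-1, up to the relative scale).

    mu_a(lambda) = ln(10) * (eps_HbO2(lambda)*C_HbO2 + eps_Hb(lambda)*C_Hb),
    linear in each concentration.
    """
    e_o = table.extinction(wavelength_nm, "HbO2")
    e_d = table.extinction(wavelength_nm, "Hb")
    return LN10 * (np.asarray(e_o) * state.c_hbo2 + np.asarray(e_d) * state.c_hb)
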