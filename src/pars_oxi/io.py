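"""File formats: TIFF images with JSON sidecars, CSV scan tables.

En-face images write as 32-bit single-channel TIFF with the validity mask
as a companion channel (masked pixels hold 0 in the data channel so viewers
behave; the mask is the authority). OCT frames write spectra as a TIFF
stack plus a JSON sidecar holding reference spectrum, k grid and
coefficients. Scan streams use the columnar CSV schema defined in
:mod:`pars_oxi.synthetic_data`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

from .pars_recon import EnFaceImage, GridSpec
from .synthetic_data import OCTFrame

PathLike = Union[str, Path]


def _sidecar(path: PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_enface(image: EnFaceImage, path: PathLike) -> None:
    """Write data + mask channels and a JSON sidecar with the grid spec."""
    data = np.stack([image.values.astype(np.float32),
                     image.valid_mask.astype(np.float32)])
    tifffile.imwrite(path, data)
    meta = {
        "grid": {"nx": image.grid.nx, "ny": image.grid.ny,
                 "pitch_um": image.grid.pitch_um,
                 "origin_um": list(image.grid.origin_um)},
        "wavelength_nm": image.wavelength_nm,
        "meta": _jsonable(image.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_enface(path: PathLike) -> EnFaceImage:
    data = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    g = meta["grid"]
    grid = GridSpec(nx=g["nx"], ny=g["ny"], pitch_um=g["pitch_um"],
                    origin_um=tuple(g["origin_um"]))
    return EnFaceImage(values=data[0].astype(float),
                       valid_mask=data[1] > 0.5, grid=grid,
                       wavelength_nm=meta.get("wavelength_nm"),
                       meta=meta.get("meta", {}))


def write_oct_frame(frame: OCTFrame, path: PathLike) -> None:
    tifffile.imwrite(path, frame.spectra.astype(np.float32))
    meta = {
        "reference_spectrum": frame.reference_spectrum.tolist(),
        "k_grid": frame.k_grid.tolist(),
        "dispersion_coeffs": list(frame.dispersion_coeffs),
        "noise_sigma": frame.noise_sigma,
        "meta": _jsonable(frame.meta),
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_oct_frame(path: PathLike) -> OCTFrame:
    spectra = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return OCTFrame(
        spectra=spectra,
        reference_spectrum=np.asarray(meta["reference_spectrum"]),
        k_grid=np.asarray(meta["k_grid"]),
        dispersion_coeffs=tuple(meta["dispersion_coeffs"]),
        noise_sigma=meta["noise_sigma"],
        meta=meta.get("meta", {}),
    )


def write_so2_map(so2: np.ndarray, path: PathLike) -> None:
    """Float TIFF, NaN where no vessel was painted."""
    tifffile.imwrite(path, so2.astype(np.float32))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
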