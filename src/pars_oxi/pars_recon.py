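"""En-face PARS image reconstruction from scattered scan records.

The acquisition yields one A-scan per laser shot at scattered (motion-
displaced) beam positions. Reconstruction is two steps:

1. maximum amplitude projection (MAP): each A-scan collapses to the maximum
   of its absolute amplitude, giving one scalar per shot;
2. Delaunay gridding: the scattered (x, y, amplitude) samples are
   triangulated and interpolated barycentrically (piecewise-linear) onto a
   regular pixel grid. Pixels outside the convex hull of the samples are
   masked invalid, never fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .synthetic_data import ScanRecord, ScanStream

__all__ = [
    "GridSpec",
    "EnFaceImage",
    "DegenerateGeometryError",
    "map_project",
    "grid_interpolate",
    "reconstruct",
    "measure_snr",
]


class DegenerateGeometryError(ValueError):
    """Sample points do not admit a 2-D triangulation (e.g. all collinear)."""


@dataclass(frozen=True)
class GridSpec:
    """Regular reconstruction grid: origin (um), pixel pitch (um), size."""

    nx: int
    ny: int
    pitch_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @classmethod
    def from_fov(cls, fov: tuple[float, float], pixels: int = 512) -> "GridSpec":
        """Square-pixel grid covering a (width, height) um field of view."""
        w, h = fov
        pitch = max(w, h) / (pixels - 1)
        return cls(nx=int(round(w / pitch)) + 1, ny=int(round(h / pitch)) + 1,
                   pitch_um=pitch)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin_um
        return (x0 + np.arange(self.nx) * self.pitch_um,
                y0 + np.arange(self.ny) * self.pitch_um)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = self.axes()
        return np.meshgrid(xs, ys)


@dataclass
class EnFaceImage:
    """Regular-grid en-face image with a validity mask.

    ``values`` is (ny, nx), finite and non-negative wherever ``valid_mask``
    is True; pixels outside the interpolation hull are masked and hold 0.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    grid: GridSpec
    wavelength_nm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("image shape inconsistent with grid spec")
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite on the valid mask")


def map_project(record: Union[ScanRecord, np.ndarray]) -> float:
    """Maximum amplitude projection of one A-scan: max |trace|.

    Invariant to a global sign flip of the trace.
    """
    trace = record.trace if isinstance(record, ScanRecord) else np.asarray(record)
    if trace.size == 0:
        raise ValueError("cannot project an empty trace")
    return float(np.max(np.abs(trace)))


def _dedupe(points: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average amplitudes at exactly repeated positions (dwell shots).

    Always returns the points in canonical (lexicographic) order, so the
    downstream triangulation -- whose tie-breaking on co-circular point
    sets depends on input order -- is permutation invariant.
    """
    uniq, inverse, counts = np.unique(points, axis=0, return_inverse=True,
                                      return_counts=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, values)
    avg = summed / counts
    dup_vals = counts > 1
    # only warn when duplicates actually disagree
    spread = np.zeros(len(uniq))
    np.add.at(spread, inverse, (values - avg[inverse]) ** 2)
    if np.any(spread[dup_vals] > 0):
        warnings.warn(
            f"{int(dup_vals.sum())} duplicated sample positions with differing "
            "amplitudes were averaged", stacklevel=3)
    return uniq, avg


def grid_interpolate(points, grid_spec: GridSpec,
                     wavelength_nm: Optional[float] = None,
                     meta: Optional[dict] = None) -> EnFaceImage:
    """Delaunay-triangulate scattered samples and grid them linearly.

    ``points`` is (n, 3): x um, y um, amplitude. Each grid node inside the
    convex hull receives the barycentric-linear interpolant of its
    containing triangle (exact at nodes coinciding with samples); nodes
    outside the hull are masked invalid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of x, y, amplitude")
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least 3 sample points")
    xy, amp = _dedupe(pts[:, :2], pts[:, 2])
    try:
        tri = Delaunay(xy)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "sample points are degenerate (collinear or coincident); "
            "cannot triangulate") from exc
    interp = LinearNDInterpolator(tri, amp)
    gx, gy = grid_spec.mesh()
    vals = interp(gx, gy)
    mask = np.isfinite(vals)
    vals = np.where(mask, vals, 0.0)
    return EnFaceImage(values=vals, valid_mask=mask, grid=grid_spec,
                       wavelength_nm=wavelength_nm, meta=dict(meta or {}))


def reconstruct(stream: ScanStream, grid_spec: GridSpec,
                wavelength_nm: float, use_commanded: bool = False) -> EnFaceImage:
    """MAP-project a scan stream at one wavelength and grid it.

    Uses the *actual* (motion-displaced) beam positions by default, so
    motion shows up as geometric distortion exactly as in the instrument;
    ``use_commanded=True`` grids on the ideal raster instead.
    """
    sub = stream.select(wavelength_nm)
    amplitudes = np.max(np.abs(sub.traces), axis=1)
    xy = sub.commanded if use_commanded else sub.positions
    meta = {"source": sub.meta, "n_records": len(sub),
            "use_commanded": use_commanded}
    return grid_interpolate(np.column_stack([xy, amplitudes]), grid_spec,
                            wavelength_nm=wavelength_nm, meta=meta)


def measure_snr(image: EnFaceImage, signal_region: np.ndarray,
                background_region: np.ndarray) -> float:
    """Image SNR in dB: 20 log10(mean signal amplitude / background sd)."""
    sig = np.asarray(signal_region, dtype=bool)
    bg = np.asarray(background_region, dtype=bool)
    if sig.shape != image.values.shape or bg.shape != image.values.shape:
        raise ValueError("region masks must match the image shape")
    if np.any(sig & bg):
        raise ValueError("signal and background regions must be disjoint")
    sig = sig & image.valid_mask
    bg = bg & image.valid_mask
    if not sig.any() or not bg.any():
        raise ValueError("regions must be non-empty within the valid mask")
    mean_sig = float(image.values[sig].mean())
    sd_bg = float(image.values[bg].std(ddof=1))
    if sd_bg == 0:
        raise ValueError("background standard deviation is zero; SNR undefined")
    return 20.0 * np.log10(mean_sig / sd_bg)
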