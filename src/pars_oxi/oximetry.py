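"""Two-wavelength oxygen-saturation estimation from en-face PARS images.

The estimator is the mean-value method: within an in-focus sub-region the
per-wavelength image amplitudes are averaged to one representative value
per excitation wavelength, and the relative chromophore concentrations are
recovered by linear least squares against the hemoglobin extinction basis,

    [ eps_HbO2(l1)  eps_Hb(l1) ] [ C_HbO2 ]   [ s(l1) ]
    [ eps_HbO2(l2)  eps_Hb(l2) ] [ C_Hb   ] = [ s(l2) ]

(any common gain/fluence factor is absorbed into the relative scale of the
concentrations, so SO2 = C_HbO2/(C_HbO2+C_Hb) is scale-invariant).
Averaging before unmixing suppresses random per-pixel errors; negative
least-squares components are projected back onto the physical cone c >= 0.
SO2 maps are painted per vessel, not per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from skimage import measure as _skmeasure

from .chromophores import BloodOpticalState, ChromophoreTable
from .pars_recon import EnFaceImage

__all__ = [
    "UnmixingInput",
    "OximetryResult",
    "AccuracySummary",
    "ConditioningError",
    "UndefinedSO2Error",
    "select_focus_region",
    "mean_signal",
    "build_unmixing_input",
    "unmix",
    "segment_vessels",
    "so2_map",
    "accuracy_report",
]

#: condition-number ceiling for the extinction matrix
COND_LIMIT = 1e6


class ConditioningError(ValueError):
    """Extinction matrix is too ill-conditioned to unmix (wavelengths too close)."""


class UndefinedSO2Error(ValueError):
    """Both concentrations vanished; saturation is undefined."""


@dataclass(frozen=True)
class UnmixingInput:
    """Representative mean amplitude per excitation wavelength for a region."""

    mean_amplitudes: Mapping[float, float]   # wavelength nm -> amplitude
    region_id: str = "region"
    n_pixels: int = 1

    def __post_init__(self) -> None:
        if len(self.mean_amplitudes) < 2:
            raise ValueError("need >= 2 distinct wavelengths to unmix")
        if any(v < 0 for v in self.mean_amplitudes.values()):
            raise ValueError("mean amplitudes must be non-negative")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        object.__setattr__(self, "mean_amplitudes",
                           dict(self.mean_amplitudes))


@dataclass
class OximetryResult:
    """Unmixing outcome: relative concentrations, SO2, misfit, clamp flag."""

    state: BloodOpticalState
    so2: float
    residual: float
    clamped: bool
    region_id: str = "region"
    per_pixel_map: Optional[np.ndarray] = None
    confidence_mask: Optional[np.ndarray] = None
    per_vessel: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class AccuracySummary:
    """Paired-difference summary; 'accuracy' is the sd of the differences."""

    bias: float
    sd: float
    max_abs: float
    n: int


def select_focus_region(image: EnFaceImage, percentile: float = 80.0) -> np.ndarray:
    """In-focus sub-region: bright connected component of the image.

    Keeps pixels at or above the ``percentile``-th amplitude percentile of
    the valid mask and returns the largest connected component. A uniform
    image returns the whole valid mask.
    """
    if not image.valid_mask.any():
        raise ValueError("image has no valid pixels")
    vals = image.values[image.valid_mask]
    thr = np.percentile(vals, percentile)
    cand = image.valid_mask & (image.values > thr)
    if not cand.any():
        # flat-at-threshold image (e.g. uniform): keep the at-level pixels
        cand = image.valid_mask & (image.values >= thr)
    if not cand.any():
        raise ValueError(
            f"no pixels at or above the {percentile:g}th percentile; "
            "lower the threshold")
    labels = _skmeasure.label(cand, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def mean_signal(image: EnFaceImage, region: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean amplitude over ``region`` and the pixel count."""
    region = np.asarray(region, dtype=bool)
    if region.shape != image.values.shape:
        raise ValueError("region mask must match the image shape")
    if np.any(region & ~image.valid_mask):
        raise ValueError("region extends outside the valid mask")
    n = int(region.sum())
    if n == 0:
        raise ValueError("region is empty")
    return float(image.values[region].mean()), n


def build_unmixing_input(images: Mapping[float, EnFaceImage],
                         region: np.ndarray,
                         region_id: str = "region") -> UnmixingInput:
    """Mean-value inputs from co-registered per-wavelength images."""
    means = {}
    n = 0
    for wl, img in images.items():
        m, n = mean_signal(img, region)
        means[float(wl)] = m
    return UnmixingInput(mean_amplitudes=means, region_id=region_id, n_pixels=n)


def unmix(inputs: UnmixingInput, table: ChromophoreTable,
          gains: Optional[Mapping[float, float]] = None) -> OximetryResult:
    """Least-squares spectral unmixing of mean amplitudes into HbO2/Hb.

    For exactly two wavelengths this reduces to the closed-form 2x2 solve.
    A solution with a negative component is projected onto the physical
    cone c >= 0 (non-negative least squares) and flagged ``clamped``.
    ``gains`` is a per-wavelength calibration hook (fluence/detector
    response relative to a reference wavelength); amplitudes are divided
    by it before the solve. Default: equal gain at all wavelengths.
    """
    wavelengths = sorted(inputs.mean_amplitudes)
    s = np.array([inputs.mean_amplitudes[w] for w in wavelengths])
    if gains is not None:
        g = np.array([gains[w] for w in wavelengths], dtype=float)
        if np.any(g <= 0):
            raise ValueError("gains must be positive")
        s = s / g
    A = np.column_stack([
        [table.extinction(w, "HbO2") for w in wavelengths],
        [table.extinction(w, "Hb") for w in wavelengths],
    ])
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise ConditioningError(
            f"extinction matrix condition number {cond:.3g} exceeds "
            f"{COND_LIMIT:g}; wavelengths {wavelengths} are too close")
    c, *_ = np.linalg.lstsq(A, s, rcond=None)
    # only a genuinely negative component (beyond round-off) triggers the
    # boundary projection; tiny numerical negatives are snapped to zero
    tol = 1e-9 * max(np.max(np.abs(c)), np.finfo(float).tiny)
    clamped = bool(np.any(c < -tol))
    if clamped:
        c, _ = nnls(A, s)
    else:
        c = np.clip(c, 0.0, None)
    total = c.sum()
    if total <= 0:
        raise UndefinedSO2Error("both concentrations are zero; SO2 undefined")
    residual = float(np.linalg.norm(A @ c - s))
    state = BloodOpticalState(c_hbo2=float(c[0]), c_hb=float(c[1]))
    return OximetryResult(state=state, so2=state.so2, residual=residual,
                          clamped=clamped, region_id=inputs.region_id)


def segment_vessels(image: EnFaceImage, threshold_percentile: float = 75.0,
                    min_pixels: int = 20) -> np.ndarray:
    """Default vessel segmentation: threshold + connected components.

    Declared plumbing, swappable: any integer label image on the same grid
    works with :func:`so2_map`.
    """
    vals = image.values[image.valid_mask]
    thr = np.percentile(vals, threshold_percentile)
    fg = image.valid_mask & (image.values >= thr) & (image.values > 0)
    labels = _skmeasure.label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_pixels)
    labels[np.isin(labels, small)] = 0
    # relabel consecutively
    return _skmeasure.label(labels > 0, connectivity=2)


def so2_map(images: Mapping[float, EnFaceImage], segmentation: np.ndarray,
            table: ChromophoreTable,
            residual_tolerance: float = 0.1) -> OximetryResult:
    """Per-vessel SO2 map from co-registered multiwavelength images.

    Every labelled vessel gets the mean-value unmixing estimate painted
    over its pixels. Vessels with zero signal at all wavelengths are
    excluded; the confidence mask drops clamped solutions and vessels whose
    relative residual exceeds ``residual_tolerance``.
    """
    imgs = {float(w): im for w, im in images.items()}
    grids = {im.grid for im in imgs.values()}
    if len(grids) != 1:
        raise ValueError("images must share one reconstruction grid")
    shape = next(iter(imgs.values())).values.shape
    seg = np.asarray(segmentation)
    if seg.shape != shape:
        raise ValueError("segmentation grid does not match the images")

    so2_img = np.full(shape, np.nan)
    confidence = np.zeros(shape, dtype=bool)
    rows = []
    ref = None
    for label in np.unique(seg):
        if label == 0:
            continue
        region = seg == label
        region &= np.logical_and.reduce([im.valid_mask for im in imgs.values()])
        if not region.any():
            continue
        inp = build_unmixing_input(imgs, region, region_id=f"vessel-{label}")
        s = np.array(list(inp.mean_amplitudes.values()))
        if np.all(s == 0):
            continue                       # no signal: excluded from the map
        res = unmix(inp, table)
        so2_img[region] = res.so2
        rel_res = res.residual / max(np.linalg.norm(s), np.finfo(float).tiny)
        ok = (not res.clamped) and rel_res <= residual_tolerance
        confidence[region] = ok
        row = {"label": int(label), "n_pixels": inp.n_pixels,
               "c_hbo2": res.state.c_hbo2, "c_hb": res.state.c_hb,
               "so2": res.so2, "residual": res.residual,
               "clamped": res.clamped}
        for w, m in sorted(inp.mean_amplitudes.items()):
            row[f"mean_{int(round(w))}"] = m
        rows.append(row)
        ref = res
    if ref is None:
        raise UndefinedSO2Error("no vessel produced a defined SO2")
    table_df = pd.DataFrame(rows)
    return OximetryResult(state=ref.state, so2=float(np.nanmean(so2_img)),
                          residual=float(table_df["residual"].max()),
                          clamped=bool(table_df["clamped"].any()),
                          region_id="map", per_pixel_map=so2_img,
                          confidence_mask=confidence, per_vessel=table_df)


def accuracy_report(estimates: Sequence[float],
                    reference: Sequence[float]) -> AccuracySummary:
    """Summarise paired SO2 differences (estimate minus reference).

    'Accuracy' follows the oximetry convention used for the in-vitro
    validation: the standard deviation of the paired differences.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or est.size < 1:
        raise ValueError("estimates and reference must be equal-length 1-D, n >= 1")
    d = est - ref
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return AccuracySummary(bias=float(d.mean()), sd=sd,
                           max_abs=float(np.abs(d).max()), n=d.size)
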