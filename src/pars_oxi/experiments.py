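"""Canned end-to-end experiments used by the analysis scripts and tests.

These functions wire the full chain -- phantom, raw-stream simulation,
en-face reconstruction, focus-region mean-value unmixing -- into the three
study-scale experiments: the in-vitro capillary saturation series, the
retina-preset SNR check, and the noiseless forward/inverse sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromophores import ChromophoreTable
from .oximetry import (AccuracySummary, accuracy_report, build_unmixing_input,
                       select_focus_region, unmix)
from .pars_recon import GridSpec, measure_snr, reconstruct
from .synthetic_data import SimConfig, generate_vessel_phantom, simulate_pars_stream

DEFAULT_WAVELENGTHS = (532.0, 558.0)


def estimate_capillary_so2(
    true_so2: float,
    seed: int,
    table: Optional[ChromophoreTable] = None,
    target_snr_db: Optional[float] = 26.0,
    raster: tuple = (80, 80, None),
    grid_pixels: int = 96,
    wavelengths: Sequence[float] = DEFAULT_WAVELENGTHS,
) -> float:
    """One capillary acquisition -> mean-value SO2 estimate.

    Simulates the blood-filled capillary phantom at ``true_so2``,
    reconstructs both excitation wavelengths, selects the in-focus
    sub-region on the first-wavelength image and unmixes the region means.
    """
    table = table or ChromophoreTable.default()
    phantom = generate_vessel_phantom("capillary", seed=seed, so2=true_so2,
                                      focus_falloff_um=120.0)
    sim = SimConfig(seed=seed, target_snr_db=target_snr_db, raster=raster)
    stream = simulate_pars_stream(phantom, table, sim, wavelengths)
    grid = GridSpec.from_fov(phantom.field_of_view, pixels=grid_pixels)
    images = {wl: reconstruct(stream, grid, wl) for wl in wavelengths}
    region = select_focus_region(images[wavelengths[0]])
    inputs = build_unmixing_input(images, region, region_id=f"capillary-{seed}")
    return unmix(inputs, table).so2


@dataclass(frozen=True)
class CapillaryExperiment:
    """Result of the repeated-acquisition capillary saturation series."""

    table: pd.DataFrame          # setpoint, seed, estimate, error
    summary: AccuracySummary     # paired estimate-vs-truth differences


def run_capillary_experiment(
    setpoints: Sequence[float] = (0.40, 0.60),
    n_repeats: int = 4,
    seeds: Optional[Sequence[int]] = None,
    table: Optional[ChromophoreTable] = None,
    target_snr_db: Optional[float] = 26.0,
) -> CapillaryExperiment:
    """The in-vitro surrogate: repeated capillary acquisitions per setpoint.

    Each acquisition covers the raster in well under 6 s of instrument
    time at the 60 kHz pulse rate. ``seeds`` supplies one seed per
    acquisition (len = len(setpoints) * n_repeats); defaults to 1..N.
    """
    chrom = table or ChromophoreTable.default()
    n_total = len(setpoints) * n_repeats
    if seeds is None:
        seeds = list(range(1, n_total + 1))
    if len(seeds) != n_total:
        raise ValueError(f"need {n_total} seeds, got {len(seeds)}")
    rows = []
    it = iter(seeds)
    for sp in setpoints:
        for _ in range(n_repeats):
            seed = int(next(it))
            est = estimate_capillary_so2(sp, seed, table=chrom,
                                         target_snr_db=target_snr_db)
            rows.append({"setpoint": sp, "seed": seed, "estimate": est,
                         "error": est - sp})
    df = pd.DataFrame(rows)
    summary = accuracy_report(df["estimate"].to_numpy(),
                              df["setpoint"].to_numpy())
    return CapillaryExperiment(table=df, summary=summary)


def retina_snr_measurement(
    seed: int,
    table: Optional[ChromophoreTable] = None,
    target_snr_db: float = 26.0,
    raster: tuple = (110, 110, None),
    grid_pixels: int = 128,
    wavelength: float = 532.0,
) -> float:
    """Measured image SNR (dB) of one retina-preset acquisition.

    The signal region is the ground-truth vessel footprint on the
    reconstruction grid; the background region is everything at least
    ~40 um away from any vessel.
    """
    chrom = table or ChromophoreTable.default()
    phantom = generate_vessel_phantom("retina", seed=seed)
    sim = SimConfig(seed=seed, target_snr_db=target_snr_db, raster=raster)
    stream = simulate_pars_stream(phantom, chrom, sim, [wavelength])
    grid = GridSpec.from_fov(phantom.field_of_view, pixels=grid_pixels)
    image = reconstruct(stream, grid, wavelength)
    gx, gy = grid.mesh()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = phantom.signal_mask(pts).reshape(image.values.shape)
    # background: clearly off-vessel (beyond one dilation margin)
    margin = 40.0
    near = np.zeros_like(inside)
    for v in phantom.vessels:
        near |= (v.distance(pts) <= v.radius_um + margin).reshape(inside.shape)
    background = ~near
    return measure_snr(image, inside, background)


def noiseless_so2_sweep(
    so2_values: Sequence[float],
    table: Optional[ChromophoreTable] = None,
    raster: tuple = (40, 40, None),
    grid_pixels: int = 48,
) -> pd.DataFrame:
    """Forward-simulate -> reconstruct -> unmix without noise, per SO2."""
    chrom = table or ChromophoreTable.default()
    rows = []
    for so2 in so2_values:
        est = estimate_capillary_so2(float(so2), seed=0, table=chrom,
                                     target_snr_db=None, raster=raster,
                                     grid_pixels=grid_pixels)
        rows.append({"true_so2": float(so2), "estimate": est,
                     "abs_error": abs(est - so2)})
    return pd.DataFrame(rows)
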