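"""ANSI ocular-exposure analysis for the scanned visible excitation laser.

Implements the point-source maximum-permissible-exposure (MPE) rules that a
retinal scanning system with nanosecond visible pulses actually exercises:

* Rule 1 - single-pulse limit: in the visible band, 1 ns-18 us pulses,
  MPE_SP = 5e-7 J/cm2 (thermal only at ns durations).
* Rule 2 - average-exposure dual limits for 0.7 s < t <= 100 s, 400-600 nm:
  photochemical MPE_ph = C_B * 1e-3 J/cm2 with C_B = 10^(0.02 (lambda-450)),
  and thermal MPE_th = 1.8 * t^0.75 * 1e-3 J/cm2 (18 us < t <= 10 s branch).
* Rule 3 - repetitive pulses: MPE_rp = n^-0.25 * MPE_SP for n pulses
  overlapping one retinal spot.

plus the spectrally flat corneal irradiance limit 25 t^-0.75 W/cm2
(t < 10 s; 4.0 W/cm2 for t > 10 s) for 380-1400 nm continuous beams.

Only the branches above are implemented; anything else raises
:class:`UnsupportedBranchError` rather than guessing standard tables.
Internally all quantities are kept at full precision; reported values are
rounded to 2-3 significant figures as safety write-ups conventionally do.

For a galvo-scanned beam, a given retinal spot sees only the ``n``
overlapping pulses during the whole exposure, so Rule 2's average radiant
exposure converts to a per-pulse equivalent by dividing by ``n``; the
``stationary_beam`` option divides by the total pulse count ``t * PRR``
instead, which is the correct conversion when the beam does not move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ExposureSpec",
    "SafetyReport",
    "UnsupportedBranchError",
    "angular_subtense",
    "mpe_single_pulse",
    "mpe_photochemical",
    "mpe_thermal",
    "mpe_repetitive",
    "max_pulse_energy",
    "corneal_irradiance_limit",
    "pulses_per_spot",
    "evaluate",
    "round_sig",
    "trunc_sig",
]

ALPHA_MIN_MRAD = 1.5


class UnsupportedBranchError(ValueError):
    """Inputs fall outside the implemented MPE rule branches."""


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def trunc_sig(x: float, sig: int) -> float:
    """Truncate toward zero to ``sig`` significant figures.

    Exposure *limits* are truncated rather than rounded: shaving a limit
    downward is the conservative direction for a safety number.
    """
    if x == 0:
        return 0.0
    ndigits = -int(math.floor(math.log10(abs(x)))) + (sig - 1)
    scale = 10.0 ** ndigits
    return math.trunc(x * scale) / scale


@dataclass(frozen=True)
class ExposureSpec:
    """Exposure geometry and source parameters; defaults are the study's."""

    wavelength_nm: float = 532.0
    pulse_duration_s: float = 1.5e-9
    prr_hz: float = 60e3
    exposure_duration_s: float = 10.0
    retinal_spot_um: float = 20.0
    eye_focal_length_mm: float = 17.0
    n_overlapping_pulses: int = 2
    pupil_diameter_cm: float = 0.7
    single_pulse_energy_J: float = 150e-9
    cw_power_W: Optional[float] = None          # detection/OCT beam power
    corneal_beam_diameter_cm: float = 0.12      # ~1.2 mm collimated beam
    stationary_beam: bool = False

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "pulse_duration_s", "prr_hz",
                     "exposure_duration_s", "retinal_spot_um",
                     "eye_focal_length_mm", "pupil_diameter_cm",
                     "single_pulse_energy_J", "corneal_beam_diameter_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_overlapping_pulses < 1:
            raise ValueError("n_overlapping_pulses must be >= 1")
        if not 380.0 <= self.wavelength_nm <= 1400.0:
            raise UnsupportedBranchError(
                "only wavelengths in [380, 1400] nm are implemented")


@dataclass(frozen=True)
class SafetyReport:
    """All computed ANSI quantities with pass/fail verdicts."""

    alpha_mrad: float
    is_point_source: bool
    mpe_sp_J_cm2: float
    mpe_ph_J_cm2: float
    mpe_th_J_cm2: float
    mpe_rp_J_cm2: float
    governing_rule: str
    governing_limit_J_cm2: float
    max_pulse_energy_J: float
    pulse_energy_pass: bool
    corneal_irradiance_limit_W_cm2: float
    cw_irradiance_W_cm2: Optional[float]
    cw_pass: Optional[bool]

    def printed(self) -> dict:
        """Quantities at the conventional reporting precision.

        Geometric quantities round to 2 significant figures; exposure
        limits truncate (see :func:`trunc_sig`).
        """
        out = {
            "alpha_mrad": round_sig(self.alpha_mrad, 2),
            "is_point_source": self.is_point_source,
            "mpe_sp_J_cm2": trunc_sig(self.mpe_sp_J_cm2, 2),
            "mpe_ph_J_cm2": trunc_sig(self.mpe_ph_J_cm2, 3),
            "mpe_th_J_cm2": trunc_sig(self.mpe_th_J_cm2, 3),
            "mpe_rp_J_cm2": trunc_sig(self.mpe_rp_J_cm2, 2),
            "governing_rule": self.governing_rule,
            "max_pulse_energy_nJ": trunc_sig(self.max_pulse_energy_J * 1e9, 2),
            "pulse_energy_pass": self.pulse_energy_pass,
            "corneal_irradiance_limit_W_cm2":
                trunc_sig(self.corneal_irradiance_limit_W_cm2, 2),
            "cw_pass": self.cw_pass,
        }
        if self.cw_irradiance_W_cm2 is not None:
            out["cw_irradiance_W_cm2"] = round_sig(self.cw_irradiance_W_cm2, 2)
        return out


def angular_subtense(retinal_spot_um: float,
                     eye_focal_length_mm: float) -> tuple[float, bool]:
    """Apparent source angle alpha (mrad) and the point-source verdict.

    alpha = spot / focal length; sources with alpha < 1.5 mrad are point
    sources. The returned alpha is rounded to 2 significant figures for
    reporting (the classification uses the full-precision value).
    """
    if retinal_spot_um <= 0 or eye_focal_length_mm <= 0:
        raise ValueError("spot size and focal length must be positive")
    alpha_mrad = retinal_spot_um / eye_focal_length_mm   # um/mm = mrad
    return round_sig(alpha_mrad, 2), alpha_mrad < ALPHA_MIN_MRAD


def mpe_single_pulse(wavelength_nm: float, pulse_duration_s: float) -> float:
    """Rule 1: single-pulse MPE, visible band, 1 ns - 18 us (thermal)."""
    if not 400.0 <= wavelength_nm <= 700.0:
        raise UnsupportedBranchError(
            f"single-pulse rule implemented for 400-700 nm only, "
            f"got {wavelength_nm:g} nm")
    if not 1e-9 <= pulse_duration_s <= 18e-6:
        raise UnsupportedBranchError(
            f"single-pulse rule implemented for 1 ns - 18 us only, "
            f"got {pulse_duration_s:g} s")
    return 5e-7


def mpe_photochemical(wavelength_nm: float, exposure_duration_s: float) -> float:
    """Rule 2, photochemical limit: C_B * 1e-3 J/cm2, C_B = 10^(0.02(l-450))."""
    if not 400.0 <= wavelength_nm <= 600.0:
        raise UnsupportedBranchError(
            f"photochemical limit implemented for 400-600 nm, "
            f"got {wavelength_nm:g} nm")
    if not 0.7 < exposure_duration_s <= 100.0:
        raise UnsupportedBranchError(
            f"photochemical limit implemented for 0.7 s < t <= 100 s, "
            f"got {exposure_duration_s:g} s")
    c_b = 10.0 ** (0.02 * (wavelength_nm - 450.0))
    return c_b * 1e-3


def mpe_thermal(exposure_duration_s: float) -> float:
    """Rule 2, thermal limit: 1.8 t^0.75 * 1e-3 J/cm2 (18 us < t <= 10 s).

    The branch is extended through the photochemical window (t <= 100 s) so
    the dual-limit comparison stays expressible; beyond that it errs.
    """
    if not 18e-6 < exposure_duration_s <= 100.0:
        raise UnsupportedBranchError(
            f"thermal limit implemented for 18 us < t <= 100 s, "
            f"got {exposure_duration_s:g} s")
    return 1.8 * exposure_duration_s ** 0.75 * 1e-3


def mpe_repetitive(n_pulses: int, mpe_sp: float) -> float:
    """Rule 3: repetitive-pulse correction n^-0.25 applied to MPE_SP."""
    if int(n_pulses) != n_pulses or n_pulses < 1:
        raise ValueError("n_pulses must be an integer >= 1")
    return n_pulses ** -0.25 * mpe_sp


def max_pulse_energy(mpe_rp_J_cm2: float, pupil_diameter_cm: float) -> float:
    """Per-pulse energy limit through the pupil: MPE_rp * pi (D/2)^2."""
    if mpe_rp_J_cm2 < 0 or pupil_diameter_cm <= 0:
        raise ValueError("MPE must be >= 0 and pupil diameter positive")
    return mpe_rp_J_cm2 * math.pi * (pupil_diameter_cm / 2.0) ** 2


def corneal_irradiance_limit(exposure_duration_s: float) -> float:
    """Spectrally flat corneal limit: 25 t^-0.75 W/cm2 (t <= 10 s), else 4.0."""
    if exposure_duration_s <= 0:
        raise ValueError("exposure duration must be positive")
    if exposure_duration_s <= 10.0:
        return 25.0 * exposure_duration_s ** -0.75
    return 4.0


def pulses_per_spot(retinal_spot_um: float, raster_step_um: float) -> int:
    """Convenience: pulses overlapping one spot, ceil(spot / step)."""
    if retinal_spot_um <= 0 or raster_step_um <= 0:
        raise ValueError("spot size and raster step must be positive")
    return int(math.ceil(retinal_spot_um / raster_step_um))


def evaluate(spec: ExposureSpec) -> SafetyReport:
    """Run every applicable rule and identify the governing per-pulse limit.

    Rule 2's average radiant exposure is converted to a per-pulse
    equivalent by dividing by the number of pulses a retinal spot receives
    (``n_overlapping_pulses`` for the scanned beam; ``t * PRR`` when
    ``stationary_beam``). The governing rule is the minimum per-pulse
    limit; the pulse-energy verdict compares the source's single-pulse
    energy against that limit scaled by the pupil area.
    """
    alpha, point = angular_subtense(spec.retinal_spot_um,
                                    spec.eye_focal_length_mm)
    if not point:
        raise UnsupportedBranchError(
            f"alpha = {alpha:g} mrad >= {ALPHA_MIN_MRAD:g} mrad: extended "
            "sources are not implemented")

    try:
        mpe_sp = mpe_single_pulse(spec.wavelength_nm, spec.pulse_duration_s)
    except UnsupportedBranchError as exc:
        raise UnsupportedBranchError(f"Rule 1 not applicable: {exc}") from exc
    try:
        mpe_ph = mpe_photochemical(spec.wavelength_nm, spec.exposure_duration_s)
        mpe_th = mpe_thermal(spec.exposure_duration_s)
    except UnsupportedBranchError as exc:
        raise UnsupportedBranchError(f"Rule 2 not applicable: {exc}") from exc
    mpe_rp = mpe_repetitive(spec.n_overlapping_pulses, mpe_sp)

    if spec.stationary_beam:
        n_spot = spec.exposure_duration_s * spec.prr_hz
    else:
        n_spot = float(spec.n_overlapping_pulses)
    rule2_per_pulse = min(mpe_ph, mpe_th) / n_spot

    per_pulse_limits = {
        "Rule 1": mpe_sp,
        "Rule 2": rule2_per_pulse,
        "Rule 3": mpe_rp,
    }
    governing_rule = min(per_pulse_limits, key=per_pulse_limits.get)
    governing = per_pulse_limits[governing_rule]

    energy_limit = max_pulse_energy(governing, spec.pupil_diameter_cm)
    energy_pass = spec.single_pulse_energy_J <= energy_limit

    irr_limit = corneal_irradiance_limit(spec.exposure_duration_s)
    cw_irr = cw_pass = None
    if spec.cw_power_W is not None:
        beam_area = math.pi * (spec.corneal_beam_diameter_cm / 2.0) ** 2
        cw_irr = spec.cw_power_W / beam_area
        cw_pass = cw_irr <= irr_limit

    return SafetyReport(
        alpha_mrad=alpha, is_point_source=point,
        mpe_sp_J_cm2=mpe_sp, mpe_ph_J_cm2=mpe_ph, mpe_th_J_cm2=mpe_th,
        mpe_rp_J_cm2=mpe_rp, governing_rule=governing_rule,
        governing_limit_J_cm2=governing,
        max_pulse_energy_J=energy_limit, pulse_energy_pass=energy_pass,
        corneal_irradiance_limit_W_cm2=irr_limit,
        cw_irradiance_W_cm2=cw_irr, cw_pass=cw_pass,
    )
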