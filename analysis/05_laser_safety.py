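#!/usr/bin/env python
"""Ocular light-safety budget of the imaging system: the three ANSI MPE
rules for the scanned 532 nm nanosecond excitation, the pupil-area pulse
energy limit, and the spectrally flat corneal irradiance limit for the
continuous detection/OCT beams."""

import json
from pathlib import Path

from pars_oxi.laser_safety import ExposureSpec, evaluate

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = ExposureSpec(cw_power_W=3e-3)   # PARS detection beam, 3 mW worst case
    report = evaluate(spec)
    printed = report.printed()

    out = RESULTS / "safety_report.json"
    out.write_text(json.dumps({
        "exposure": {
            "wavelength_nm": spec.wavelength_nm,
            "pulse_duration_ns": spec.pulse_duration_s * 1e9,
            "prr_khz": spec.prr_hz / 1e3,
            "exposure_duration_s": spec.exposure_duration_s,
            "retinal_spot_um": spec.retinal_spot_um,
            "n_overlapping_pulses": spec.n_overlapping_pulses,
            "pupil_diameter_cm": spec.pupil_diameter_cm,
            "single_pulse_energy_nJ": spec.single_pulse_energy_J * 1e9,
            "cw_power_mW": spec.cw_power_W * 1e3,
        },
        "printed": printed,
    }, indent=2))

    print(f"angular subtense: {printed['alpha_mrad']} mrad "
          f"({'point' if printed['is_point_source'] else 'extended'} source)")
    print(f"Rule 1 MPE_SP = {printed['mpe_sp_J_cm2']:.1e} J/cm2")
    print(f"Rule 2 MPE_ph = {printed['mpe_ph_J_cm2']:.3g} J/cm2, "
          f"MPE_th = {printed['mpe_th_J_cm2']:.3g} J/cm2")
    print(f"Rule 3 MPE_rp = {printed['mpe_rp_J_cm2']:.1e} J/cm2 "
          f"(governing: {printed['governing_rule']})")
    print(f"pulse energy limit {printed['max_pulse_energy_nJ']:.0f} nJ; "
          f"{spec.single_pulse_energy_J * 1e9:.0f} nJ pulses "
          f"{'PASS' if printed['pulse_energy_pass'] else 'FAIL'}")
    print(f"corneal irradiance limit {printed['corneal_irradiance_limit_W_cm2']} "
          f"W/cm2 at t = {spec.exposure_duration_s:g} s; "
          f"{spec.cw_power_W * 1e3:g} mW detection beam "
          f"({printed['cw_irradiance_W_cm2']} W/cm2) "
          f"{'PASS' if printed['cw_pass'] else 'FAIL'}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
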