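"""End-to-end runs: YAML-configured stage execution, manifests, fixtures.

A :class:`RunConfig` names an ordered list of stages (simulate ->
reconstruct -> oximetry; simulate-oct -> oct; safety), each with a
parameter block. ``run_pipeline`` executes them into an output directory
and writes a manifest (parameters, seed, outputs with SHA-256 digests)
sufficient to re-run bit-identically. ``make_fixtures`` materialises the
named phantom presets on disk for tests and demos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .chromophores import ChromophoreTable
from .laser_safety import ExposureSpec, evaluate
from .oct_recon import estimate_dispersion, subtract_reference, transform_to_depth
from .oximetry import segment_vessels, so2_map
from .pars_recon import GridSpec, reconstruct
from .synthetic_data import (OCTFrameSpec, ScanStream, SimConfig,
                             generate_fiber_phantom, generate_vessel_phantom,
                             simulate_oct_frame, simulate_pars_stream)

log = logging.getLogger("pars_oxi.pipeline")

PathLike = Union[str, Path]

STAGE_TYPES = ("simulate", "reconstruct", "oximetry", "simulate-oct", "oct",
               "safety")

_REQUIRED_KEYS = {
    "simulate": {"preset"},
    "reconstruct": {"stream", "wavelengths"},
    "oximetry": {"images"},
    "simulate-oct": {"scene"},
    "oct": {"frame"},
    "safety": set(),
}

PRESETS = ("capillary-40", "capillary-60", "retina", "fiber-human-eye",
           "fiber-rat-eye", "oct-two-layer")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Ordered stage list with parameter blocks plus global seed/output."""

    stages: list[dict]
    seed: int = 0
    output_dir: PathLike = "pipeline_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        missing = [k for k in ("stages",) if k not in raw]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        stages = raw["stages"]
        for i, st in enumerate(stages):
            if "type" not in st:
                raise ValueError(f"stage {i} missing required keys: ['type']")
            if st["type"] not in STAGE_TYPES:
                raise ValueError(f"stage {i}: unknown type {st['type']!r}; "
                                 f"choose from {STAGE_TYPES}")
            need = _REQUIRED_KEYS[st["type"]] - set(st)
            if need:
                raise ValueError(
                    f"stage {i} ({st['type']}) missing required keys: "
                    f"{sorted(need)}")
        return cls(stages=stages, seed=int(raw.get("seed", 0)),
                   output_dir=raw.get("output_dir", "pipeline_out"),
                   log_level=raw.get("log_level", "INFO"))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _phantom_from_name(name: str, seed: int):
    if name.startswith("capillary"):
        so2 = 0.6
        if "-" in name:
            so2 = float(name.split("-")[1]) / 100.0
        return generate_vessel_phantom("capillary", seed=seed, so2=so2)
    if name == "retina":
        return generate_vessel_phantom("retina", seed=seed)
    if name.startswith("fiber"):
        return generate_fiber_phantom(name, seed=seed)
    raise ValueError(f"unknown phantom preset {name!r}; known: {PRESETS}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = ChromophoreTable.default()
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    produced: dict[str, Path] = {}

    for i, st in enumerate(config.stages):
        kind = st["type"]
        log.info("stage %d: %s", i, kind)
        entry = {"type": kind, "params": {k: v for k, v in st.items()
                                          if k != "type"}}
        try:
            if kind == "simulate":
                phantom = _phantom_from_name(st["preset"], config.seed)
                wavelengths = st.get("wavelengths", [532.0, 558.0])
                raster = tuple(st.get("raster", (80, 80, None)))
                sim = SimConfig(seed=config.seed,
                                target_snr_db=st.get("target_snr_db", 26.0),
                                raster=raster)
                stream = simulate_pars_stream(phantom, table, sim, wavelengths)
                path = out / st.get("out", "stream.csv")
                stream.to_csv(path)
                produced["stream"] = path
                entry["fov"] = list(phantom.field_of_view)
            elif kind == "reconstruct":
                path = Path(st["stream"]) if Path(st["stream"]).is_absolute() \
                    else produced.get("stream", out / st["stream"])
                stream = ScanStream.from_csv(path)
                fov = st.get("fov")
                if fov is None:
                    fov = (float(stream.positions[:, 0].max()),
                           float(stream.positions[:, 1].max()))
                grid = GridSpec.from_fov(tuple(fov), pixels=st.get("pixels", 128))
                for wl in st["wavelengths"]:
                    img = reconstruct(stream, grid, float(wl))
                    ipath = out / f"image_{int(wl)}.tif"
                    pio.write_enface(img, ipath)
                    produced[f"image_{int(wl)}"] = ipath
            elif kind == "oximetry":
                images = {}
                for wl, name in st["images"].items():
                    p = produced.get(name, out / name)
                    images[float(wl)] = pio.read_enface(p)
                first = next(iter(images.values()))
                seg = segment_vessels(first)
                res = so2_map(images, seg, table)
                mpath = out / st.get("out", "so2.tif")
                pio.write_so2_map(res.per_pixel_map, mpath)
                cpath = out / st.get("report", "so2_vessels.csv")
                res.per_vessel.to_csv(cpath, index=False)
                produced["so2_map"] = mpath
                produced["so2_vessels"] = cpath
            elif kind == "simulate-oct":
                spec = OCTFrameSpec(
                    n_alines=st.get("n_alines", 64),
                    n_samples=st.get("n_samples", 1024))
                frame = simulate_oct_frame(
                    [tuple(p) for p in st["scene"]], spec,
                    dispersion_coeffs=st.get("dispersion_coeffs",
                                             (0.0, 0.0, 0.0, 0.0)),
                    noise_sigma=st.get("noise_sigma", 0.0), seed=config.seed)
                fpath = out / st.get("out", "frame.tif")
                pio.write_oct_frame(frame, fpath)
                produced["frame"] = fpath
            elif kind == "oct":
                fpath = produced.get("frame", out / st["frame"])
                frame = pio.read_oct_frame(fpath)
                spectra = subtract_reference(frame)
                if st.get("estimate_dispersion", False):
                    model = estimate_dispersion(frame)
                    from .oct_recon import compensate_dispersion
                    spectra = compensate_dispersion(spectra, model, frame.k_grid)
                    (out / "dispersion.json").write_text(json.dumps({
                        "coeffs": list(model.coeffs),
                        "metadata": model.estimation_metadata}))
                    produced["dispersion"] = out / "dispersion.json"
                bscan = transform_to_depth(spectra, frame.k_grid)
                bpath = out / st.get("out", "bscan.tif")
                import tifffile
                tifffile.imwrite(bpath,
                                 bscan.depth_profiles.astype(np.float32))
                produced["bscan"] = bpath
            elif kind == "safety":
                params = {k: v for k, v in st.items()
                          if k not in ("type", "out")}
                report = evaluate(ExposureSpec(**params))
                spath = out / st.get("out", "safety.json")
                spath.write_text(json.dumps(
                    {**dataclasses.asdict(report),
                     "printed": report.printed()}, indent=2))
                produced["safety"] = spath
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {i} ({kind}): {exc}\n")
            raise StageError(f"stage {i} ({kind}) failed: {exc}") from exc
        manifest["stages"].append(entry)

    for name, path in produced.items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}
    for extra in sorted(out.iterdir()):
        if extra.is_file() and extra.name != "manifest.json" \
                and str(extra) not in {v["path"] for v in manifest["outputs"].values()}:
            manifest["outputs"][extra.name] = {"path": str(extra),
                                               "sha256": _digest(extra)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(preset: str, seed: int, outdir: PathLike) -> list[Path]:
    """Write a small deterministic fixture bundle for a named preset."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; known presets: "
                         f"{', '.join(PRESETS)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    table = ChromophoreTable.default()
    if preset == "oct-two-layer":
        spec = OCTFrameSpec(n_alines=64, n_samples=1024)
        depth = spec.max_depth_um
        frame = simulate_oct_frame([(0.2 * depth, 1.0), (0.45 * depth, 0.6)],
                                   spec, seed=seed)
        path = out / "frame.tif"
        pio.write_oct_frame(frame, path)
        written += [path, path.with_suffix(".tif.json")]
        return written

    phantom = _phantom_from_name(preset, seed)
    sim = SimConfig(seed=seed, raster=(64, 64, None))
    wavelengths = [532.0] if preset.startswith("fiber") else [532.0, 558.0]
    stream = simulate_pars_stream(
        phantom, None if preset.startswith("fiber") else table,
        sim, wavelengths)
    spath = out / "stream.csv"
    stream.to_csv(spath)
    written.append(spath)
    truth = {"preset": preset, "seed": seed,
             "field_of_view": list(phantom.field_of_view)}
    if hasattr(phantom, "vessels"):
        truth["vessels"] = [
            {"radius_um": v.radius_um, "so2": v.so2,
             "concentration": v.concentration,
             "centerline": v.centerline.tolist()}
            for v in phantom.vessels]
    tpath = out / "truth.json"
    tpath.write_text(json.dumps(truth))
    written.append(tpath)
    return written
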