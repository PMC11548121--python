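"""Configuration files (YAML or JSON) for cuvettes, suspensions and scenes.

Schema (all keys optional unless noted):

cuvette:      {n_surround, n_wall, n_medium, path_length_mm}
suspension:   {dp_um, sd_um, n_particle, n_medium, c}
detection:    {focal_length_mm, pinhole_illum_um, pinhole_det_um,
               mirror_aperture_mm}
fixture:      {suspension, cuvette, wavelength_nm: [start, stop, step],
               noise_sd, masked_intervals_nm, seed}
scene:        {thickness_mm, mua, mus, n, phase: {kind: hg, g} |
               {kind: mie, dp_um, sd_um, wavelength_nm}, boundary,
               n_photons, seed}

Refractive-index values may be numbers or paths to (wavelength_nm, n) CSV
dispersion tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidInputError
from .fixtures import FixtureSpec
from .monte_carlo import DetectionGeometry, MediumProperties, TransportScene
from .multireflection import CuvetteSpec
from .scattering import PhaseFunction, SphereSuspension, mie_phase_function

__all__ = [
    "load_config",
    "cuvette_from_config",
    "suspension_from_config",
    "detection_from_config",
    "fixture_from_config",
    "scene_from_config",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _index(value, wavelength_nm=None):
    """Resolve a config index entry to a scalar or per-wavelength array."""
    if isinstance(value, str):
        from .dispersion import index_at

        if wavelength_nm is None:
            raise InvalidInputError(
                "a dispersion table needs a wavelength grid to evaluate on")
        return index_at(value, wavelength_nm)
    return float(value)


def cuvette_from_config(cfg: dict, wavelength_nm=None) -> CuvetteSpec:
    c = cfg.get("cuvette", cfg)
    return CuvetteSpec(
        n_surround=_index(c.get("n_surround", 1.0), wavelength_nm),
        n_wall=_index(c.get("n_wall", 1.46), wavelength_nm),
        n_medium=_index(c.get("n_medium", 1.33), wavelength_nm),
        path_length_mm=float(c.get("path_length_mm", 10.0)),
    )


def suspension_from_config(cfg: dict) -> SphereSuspension:
    c = cfg.get("suspension", cfg)
    return SphereSuspension(
        diameter_um=float(c["dp_um"]),
        sd_um=float(c.get("sd_um", 0.0)),
        n_particle=c.get("n_particle", 1.586),
        n_medium=c.get("n_medium", 1.33),
        volume_fraction=float(c.get("c", 0.01)),
    )


def detection_from_config(cfg: dict) -> DetectionGeometry:
    c = cfg.get("detection", cfg)
    return DetectionGeometry(
        focal_length_mm=float(c.get("focal_length_mm", 152.0)),
        pinhole_illum_um=float(c.get("pinhole_illum_um", 100.0)),
        pinhole_det_um=float(c.get("pinhole_det_um", 200.0)),
        mirror_aperture_mm=float(c.get("mirror_aperture_mm", 25.4)),
    )


def fixture_from_config(cfg: dict) -> FixtureSpec:
    c = cfg.get("fixture", cfg)
    kw: dict = {}
    if "suspension" in c:
        kw["suspension"] = suspension_from_config(c)
    if "cuvette" in c:
        kw["cuvette"] = cuvette_from_config(c)
    if "wavelength_nm" in c:
        start, stop, step = c["wavelength_nm"]
        kw["wavelength_nm"] = np.arange(float(start), float(stop) + float(step) / 2,
                                        float(step))
    for key in ("noise_sd", "seed", "baseline"):
        if key in c:
            kw[key] = c[key]
    if "masked_intervals_nm" in c:
        kw["masked_intervals_nm"] = tuple(tuple(map(float, iv))
                                          for iv in c["masked_intervals_nm"])
    return FixtureSpec(**kw)


def _phase_from_config(cfg: dict) -> PhaseFunction | None:
    if cfg is None:
        return None
    kind = cfg.get("kind", "hg")
    if kind == "hg":
        return PhaseFunction.hg(float(cfg["g"]))
    if kind == "mie":
        susp = SphereSuspension(
            diameter_um=float(cfg["dp_um"]),
            sd_um=float(cfg.get("sd_um", 0.0)),
            n_particle=cfg.get("n_particle", 1.586),
            n_medium=cfg.get("n_medium", 1.33),
            volume_fraction=0.01,
        )
        return mie_phase_function(susp, float(cfg.get("wavelength_nm", 600.0)))
    raise InvalidInputError(f"unknown phase-function kind {kind!r}")


def scene_from_config(cfg: dict) -> TransportScene:
    c = cfg.get("scene", cfg)
    boundary = c.get("boundary", "matched")
    if isinstance(boundary, dict):
        boundary = cuvette_from_config(boundary)
    return TransportScene(
        thickness_mm=float(c.get("thickness_mm", 10.0)),
        medium=MediumProperties(mua=float(c.get("mua", 0.0)),
                                mus=float(c.get("mus", 0.0)),
                                n=float(c.get("n", 1.33))),
        phase=_phase_from_config(c.get("phase")),
        boundary=boundary,
        detection=detection_from_config(c),
        n_photons=int(c.get("n_photons", 1_000_000)),
        seed=int(c.get("seed", 0)),
    )
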