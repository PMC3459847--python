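"""TOML configuration files for simulations, optics and scans.

Layout::

    [geometry]
    radius = 0.5          # µm
    length = 2.0          # µm initial cylindrical length

    [kinetics]
    k_on = 0.004          # µm^-2 s^-1
    k_ins = 0.00064       # µm^2 s^-1
    t_double = 5400.0     # s; or give tau directly

    [schedule]
    phases = [[900.0, "light"], [4500.0, "dark"]]

    [output]
    t_end = 5400.0
    snapshot_times = [900.0, 5400.0]

    [seed]
    value = 1

Optional ``[optics]`` and ``[scan]`` tables configure rendering and
parameter screening.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .optics import NoiseModel, OpticsConfig
from .scan import ScanGrid
from .simulator import LabelSchedule, SimulationConfig

__all__ = ["load_config", "load_simulation_config", "load_optics_config", "load_scan_grid"]


def _read(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def load_simulation_config(raw: dict) -> SimulationConfig:
    geo = raw.get("geometry", {})
    kin = raw.get("kinetics", {})
    sch = raw.get("schedule", {})
    out = raw.get("output", {})
    seed = raw.get("seed", {})
    schedule = (
        LabelSchedule(tuple((float(d), str(l)) for d, l in sch["phases"]))
        if "phases" in sch
        else LabelSchedule()
    )
    return SimulationConfig(
        k_on=float(kin.get("k_on", 0.004)),
        k_ins=float(kin.get("k_ins", 0.00064)),
        tau=float(kin["tau"]) if "tau" in kin else None,
        t_double=float(kin["t_double"]) if "t_double" in kin else (
            None if "tau" in kin else 5400.0
        ),
        radius=float(geo.get("radius", 0.5)),
        length=float(geo.get("length", 2.0)),
        schedule=schedule,
        t_end=float(out.get("t_end", 5400.0)),
        snapshot_times=tuple(float(t) for t in out.get("snapshot_times", (900.0, 5400.0))),
        max_dt=float(out.get("max_dt", 0.5)),
        seed=int(seed["value"]) if "value" in seed else None,
        track_patches=bool(out.get("track_patches", True)),
        scheme=str(out.get("scheme", "euler")),
        n_images=int(out.get("n_images", 21)),
    )


def load_optics_config(raw: dict) -> OpticsConfig:
    opt = raw.get("optics", {})
    noise = opt.get("noise", {})
    return OpticsConfig(
        na=float(opt.get("na", 1.4)),
        wavelength_nm=float(opt.get("wavelength_nm", 575.0)),
        magnification=float(opt.get("magnification", 100.0)),
        camera_pixel_um=float(opt.get("camera_pixel_um", 6.8)),
        psf_model=str(opt.get("psf_model", "gaussian")),
        z_layers=int(opt.get("z_layers", 13)),
        oversample=int(opt.get("oversample", 4)),
        margin_um=float(opt.get("margin_um", 0.5)),
        noise=NoiseModel(
            photon_scale=float(noise.get("photon_scale", 200.0)),
            read_noise=float(noise.get("read_noise", 2.0)),
            offset=float(noise.get("offset", 100.0)),
        ),
    )


def load_scan_grid(raw: dict) -> ScanGrid:
    sc = raw["scan"]
    return ScanGrid(
        pairs=tuple((float(a), float(b)) for a, b in sc["pairs"]),
        t_double=float(sc.get("t_double", 5400.0)),
        replicates=int(sc.get("replicates", 21)),
        base_seed=int(sc.get("base_seed", 0)),
    )


def load_config(path: str | Path) -> dict:
    """Parse a TOML file into the package's config objects.

    Returns a dict with keys ``simulation``, ``optics`` and (if a [scan]
    table is present) ``scan``.
    """
    raw = _read(path)
    cfg = {
        "simulation": load_simulation_config(raw),
        "optics": load_optics_config(raw),
    }
    if "scan" in raw:
        cfg["scan"] = load_scan_grid(raw)
    return cfg
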