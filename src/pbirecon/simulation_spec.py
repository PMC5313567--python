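"""Parameter-file front end for the simulator.

Uses the same YAML syntax as the reconstruction workflow file, under a
``simulate`` mapping: acquisition geometry, detector size, the ellipse
phantom, the corruption model and the output container.  The written
dataset is a regular projection-set container that any workflow can then
reconstruct.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io_formats
from .core import Geometry, ProjectionSet, ScanMode
from .simulator import (
    CorruptionModel,
    EllipseSpec,
    make_drift_components,
    simulate_half_acquisition,
    simulate_scan,
)

__all__ = ["parse_simulation", "run_simulation", "build_corruption"]

_DEF_GEOM = {"energy": 40.0, "pixel_size": 3.05e-6, "distance": 2.2,
             "n_angles": 360, "scan_mode": "half_turn_180"}
_DEF_DET = {"width": 128, "height": 1}
_DEF_FLATS = {"before": 8, "after": 0, "darks": 2}


def build_corruption(
    cfg: dict, frame_shape: tuple, n_frames: int, seed: int
) -> CorruptionModel | None:
    """Corruption model from its parameter-file section (None = ideal)."""
    if not cfg:
        return None
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    gain = np.ones((h, w))
    n_stripes = int(cfg.get("stripe_columns", 0))
    if n_stripes:
        cols = rng.choice(w, size=min(n_stripes, w), replace=False)
        gain[:, cols] *= float(cfg.get("stripe_gain", 1.03))
    comps = make_drift_components(
        (h, w), n_frames,
        n_components=int(cfg.get("drift_components", 0) or 0),
        amplitude=float(cfg.get("drift_amplitude", 0.03)),
        seed=seed + 1,
    ) if cfg.get("drift_components") else []
    return CorruptionModel(
        gain_map=gain,
        drift_components=comps,
        photon_count=float(cfg.get("photon_count", 1.0e4)),
        dark_level=float(cfg.get("dark_level", 0.0)),
        seed=seed,
        poisson=bool(cfg.get("poisson", True)),
    )


def parse_simulation(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "simulate" not in doc:
        raise ValueError("the simulation file must contain a 'simulate' mapping")
    return doc["simulate"]


def run_simulation(sim: dict, seed: int | None = None) -> tuple[ProjectionSet, Path | None]:
    """Build the simulated projection set a ``simulate`` section describes.

    Returns the set and, if an ``output`` section is present, writes the
    container and returns its path as well.
    """
    g = {**_DEF_GEOM, **(sim.get("geometry") or {})}
    det = {**_DEF_DET, **(sim.get("detector") or {})}
    flats = {**_DEF_FLATS, **(sim.get("flats") or {})}
    mode = ScanMode(g["scan_mode"])
    full = 360.0 if mode is ScanMode.FULL_TURN_360_OFFSET else 180.0
    angles = np.linspace(0.0, full, int(g["n_angles"]), endpoint=False)
    width, height = int(det["width"]), int(det["height"])
    ellipses = [EllipseSpec(**e) for e in (sim.get("phantom") or [])]
    if seed is None:
        seed = int(sim.get("seed", 0))
    n_frames = int(g["n_angles"]) + int(flats["before"]) + int(flats["after"])
    corruption = build_corruption(
        sim.get("corruption") or {}, (height, width), n_frames, seed
    )
    geometry = Geometry(
        energy=float(g["energy"]),
        pixel_size=float(g["pixel_size"]),
        distance=float(g["distance"]),
        angles=angles,
        axis_position=float(sim.get("axis_position", (width - 1) / 2.0)),
        scan_mode=mode,
    )
    common = dict(
        height=height,
        corruption=corruption,
        n_flats_before=int(flats["before"]),
        n_flats_after=int(flats["after"]),
        n_darks=int(flats["darks"]),
    )
    if mode is ScanMode.FULL_TURN_360_OFFSET:
        ps = simulate_half_acquisition(
            ellipses, geometry, float(sim.get("axis_offset", 0.0)), width, **common
        )
    else:
        ps = simulate_scan(ellipses, geometry, width, **common)
    out = sim.get("output") or {}
    path = None
    if out.get("path"):
        layout = io_formats.DatasetLayout(container=out.get("container", "hdf5"))
        path = Path(out["path"])
        io_formats.write_projection_set(ps, path, layout)
    return ps, path
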