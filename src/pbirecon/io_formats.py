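"""Read/write projection stacks, sinograms and slices in standard formats.

Two on-disk containers are supported, selectable through
:class:`DatasetLayout`:

* **HDF5** following the data-exchange convention by default
  (``exchange/data``, ``exchange/data_white``, ``exchange/data_dark``,
  ``exchange/theta``), with configurable group names;
* **TIFF sequences**: one grayscale, uncompressed TIFF per frame, with
  zero-padded numeric suffixes so that lexicographic order equals
  acquisition (and therefore angle) order.

All array payloads round-trip bit-exactly; input bit depths (e.g. 16-bit
unsigned counts) are widened losslessly to float32 on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import Geometry, ProjectionSet, ReconSlice, SliceQuantity

__all__ = [
    "DatasetLayout",
    "read_projection_set",
    "write_projection_set",
    "read_slice",
    "write_slice",
]


@dataclass
class DatasetLayout:
    """Where the four dataset components live inside a container.

    For HDF5 the fields are group/dataset paths; for a TIFF sequence they
    are file-name prefixes inside the dataset directory (frames are
    ``<prefix>_<index>.tif`` with zero-padded indices).
    """

    container: str = "hdf5"
    data: str = "exchange/data"
    white: str = "exchange/data_white"
    dark: str = "exchange/data_dark"
    theta: str = "exchange/theta"

    def __post_init__(self) -> None:
        if self.container not in ("hdf5", "tiff_sequence"):
            raise ValueError(f"unknown container {self.container!r}")
        for name in ("data", "white", "dark", "theta"):
            if not getattr(self, name):
                raise ValueError(f"layout field {name!r} must be a non-empty name")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetLayout":
        return cls(**d)


class FormatError(ValueError):
    """Malformed or inconsistent dataset container."""


def _as_float(arr: np.ndarray) -> np.ndarray:
    """Widen integer counts losslessly to float32; keep float dtypes as-is."""
    if np.issubdtype(arr.dtype, np.floating):
        return arr
    return arr.astype(np.float32)


def _split_flats(flats: np.ndarray, n_before: int) -> tuple[np.ndarray, np.ndarray]:
    n_before = int(np.clip(n_before, 0, flats.shape[0]))
    return flats[:n_before], flats[n_before:]


def write_projection_set(ps: ProjectionSet, path: str | Path, layout: DatasetLayout) -> None:
    """Persist a projection set; the inverse of :func:`read_projection_set`.

    Geometry metadata (energy, pixel size, distance, axis, scan mode) and
    the before/after split of the flats are stored alongside the arrays.
    """
    path = Path(path)
    meta = ps.geometry.to_dict()
    meta["n_flats_before"] = int(ps.flats_before.shape[0])
    if layout.container == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset(layout.data, data=ps.projections)
            f.create_dataset(layout.white, data=ps.flats)
            f.create_dataset(layout.dark, data=ps.darks)
            f.create_dataset(layout.theta, data=ps.geometry.angles)
            f.attrs["geometry"] = json.dumps(meta)
        return
    path.mkdir(parents=True, exist_ok=True)
    for prefix, stack in (
        (layout.data, ps.projections),
        (layout.white, ps.flats),
        (layout.dark, ps.darks),
    ):
        for i, frame in enumerate(stack):
            frame = np.ascontiguousarray(frame)
            target = path / f"{prefix}_{i:05d}.tif"
            target.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(target, frame)
    (path / "geometry.json").write_text(json.dumps(meta, indent=1))


def read_projection_set(path: str | Path, layout: DatasetLayout) -> ProjectionSet:
    """Load a projection set written by :func:`write_projection_set`.

    Frames are widened to float32 (lossless for <=24-bit integer counts);
    projections keep acquisition order.  Flats are split into before/after
    groups if the metadata records the split, otherwise all are "before".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout.container == "hdf5":
        with h5py.File(path, "r") as f:
            for name, key in (("data", layout.data), ("white", layout.white), ("dark", layout.dark)):
                if key not in f:
                    raise FormatError(f"missing group {key!r} ({name}) in {path}")
            projections = _as_float(np.asarray(f[layout.data]))
            flats = _as_float(np.asarray(f[layout.white]))
            darks = _as_float(np.asarray(f[layout.dark]))
            meta = json.loads(f.attrs["geometry"])
            if layout.theta in f:
                meta["angles"] = np.asarray(f[layout.theta], dtype=float)
    else:
        def load(prefix: str, what: str) -> np.ndarray:
            # match only <prefix>_<digits>.tif so e.g. a "data" prefix does
            # not swallow the "data_white" frames
            files = sorted(
                f for f in path.glob(f"{prefix}_*.tif")
                if f.stem[len(Path(prefix).name) + 1:].isdigit()
            )
            if not files:
                raise FormatError(f"missing group {prefix!r} ({what}) in {path}")
            frames = [tifffile.imread(f) for f in files]
            shapes = {fr.shape for fr in frames}
            if len(shapes) > 1:
                raise FormatError(f"inconsistent frame shapes in {prefix!r}: {shapes}")
            return _as_float(np.stack(frames))

        projections = load(layout.data, "data")
        flats = load(layout.white, "white")
        darks = load(layout.dark, "dark")
        meta_file = path / "geometry.json"
        if not meta_file.exists():
            raise FormatError(f"missing geometry.json in {path}")
        meta = json.loads(meta_file.read_text())
    n_before = int(meta.pop("n_flats_before", flats.shape[0]))
    geometry = Geometry.from_dict(meta)
    fb, fa = _split_flats(flats, n_before)
    try:
        return ProjectionSet(
            projections=projections,
            flats_before=fb,
            flats_after=fa,
            darks=darks,
            geometry=geometry,
        )
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_slice(slice_: ReconSlice, path: str | Path) -> None:
    """Write a reconstructed slice as an uncompressed 32-bit float TIFF.

    The physical quantity and pixel size are stored in the TIFF
    description tag; NaN pixels are rejected.
    """
    if not np.all(np.isfinite(slice_.values)):
        raise ValueError("slice contains non-finite pixels")
    desc = json.dumps(
        {"quantity": slice_.quantity.value, "pixel_size": slice_.pixel_size}
    )
    tifffile.imwrite(
        Path(path), slice_.values.astype(np.float32), description=desc
    )


def read_slice(path: str | Path) -> ReconSlice:
    """Read a slice written by :func:`write_slice` (bit-exact round-trip)."""
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return ReconSlice(
        values=values,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        quantity=SliceQuantity(meta.get("quantity", "attenuation_coefficient")),
    )
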