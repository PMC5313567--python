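"""Domain types, units and physical conversions shared by all pipeline stages.

The optical model throughout the package is the complex X-ray refractive
index ``n = 1 - delta + i*beta``: ``delta`` (the decrement from unity)
governs the phase shift imparted to the wavefield, ``beta`` the absorption.
All lengths are metres, photon energies keV, rotation angles degrees.

Coordinate conventions
----------------------
Images use 0-based indices with pixel-center coordinates.  The rotation
axis position (``axis_position``) is a *float* detector-column index in
this convention; the detector centre of a width-``W`` frame is
``(W - 1) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "HC_KEV_M",
    "ScanMode",
    "SliceQuantity",
    "Geometry",
    "RefractiveMap",
    "ProjectionSet",
    "Sinogram",
    "ReconSlice",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "fresnel_number",
    "ContactRegime",
]

#: h*c in keV.m (CODATA: hc = 1239.84193 eV.nm).
HC_KEV_M = 1.23984193e-9


class ScanMode(str, Enum):
    """Acquisition geometry of the rotation scan."""

    #: conventional scan: angles covering [0, 180) with the axis anywhere
    #: on the detector.
    HALF_TURN_180 = "half_turn_180"
    #: extended field-of-view ("half acquisition") scan: a full 360-degree
    #: turn with the rotation axis offset towards one detector edge; rows
    #: theta and theta+180 are later stitched into wide 180-degree rows.
    FULL_TURN_360_OFFSET = "full_turn_360_offset"


class SliceQuantity(str, Enum):
    """Physical quantity carried by a reconstructed slice."""

    ATTENUATION_COEFFICIENT = "attenuation_coefficient"
    DELTA = "delta"
    PHASE = "phase"


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in metres for an energy in keV.

    ``lambda = h c / E``; e.g. 40 keV -> 3.0996e-11 m.
    """
    if not np.all(np.asarray(energy_kev) > 0):
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_M / energy_kev


def wavelength_to_energy(wavelength_m: float) -> float:
    """Inverse of :func:`energy_to_wavelength` (keV for a wavelength in m)."""
    if not np.all(np.asarray(wavelength_m) > 0):
        raise ValueError(f"wavelength must be positive, got {wavelength_m}")
    return HC_KEV_M / wavelength_m


class ContactRegime(float):
    """Marker for an infinite Fresnel number (zero propagation distance).

    Behaves as ``float('inf')`` but is distinguishable via isinstance so
    callers can detect the contact (pure absorption) regime.
    """

    def __new__(cls) -> "ContactRegime":
        return super().__new__(cls, math.inf)


@dataclass
class Geometry:
    """Acquisition geometry of a parallel-beam propagation-based scan.

    Parameters
    ----------
    energy : float
        Photon energy, keV (monochromatic beam assumed).
    pixel_size : float
        Detector pixel size, metres.
    distance : float
        Sample-to-detector (free-space propagation) distance, metres.
        ``0`` is the contact regime: pure attenuation contrast.
    angles : array-like
        Ordered rotation angles in degrees, strictly increasing, one per
        projection.
    axis_position : float
        Rotation-axis column in fractional pixels (0-based, pixel-center).
    scan_mode : ScanMode
        Conventional 180-degree scan or offset-axis 360-degree scan.
    """

    energy: float
    pixel_size: float
    distance: float
    angles: np.ndarray
    axis_position: float
    scan_mode: ScanMode = ScanMode.HALF_TURN_180

    def __post_init__(self) -> None:
        self.scan_mode = ScanMode(self.scan_mode)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.energy <= 0:
            raise ValueError("energy must be > 0 keV")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 m")
        if self.distance < 0:
            raise ValueError("distance must be >= 0 m")
        if self.angles.ndim != 1 or self.angles.size == 0:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if self.angles.size > 1:
            steps = np.diff(self.angles)
            if np.any(steps <= 0):
                raise ValueError("angles must be strictly increasing")
            span = self.angles[-1] - self.angles[0]
            # tolerate the missing end-point of a half-open uniform grid
            eps = 2.0 * float(np.median(steps))
            required = 180.0 if self.scan_mode is ScanMode.HALF_TURN_180 else 360.0
            if span < required - eps:
                raise ValueError(
                    f"angle span {span:.3f} deg is below the {required:.0f} deg "
                    f"required for scan mode {self.scan_mode.value}"
                )

    @property
    def wavelength(self) -> float:
        """Photon wavelength, metres (``hc / E``)."""
        return energy_to_wavelength(self.energy)

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles)

    def replace(self, **kwargs) -> "Geometry":
        """Return a copy with some fields replaced."""
        params = dict(
            energy=self.energy,
            pixel_size=self.pixel_size,
            distance=self.distance,
            angles=self.angles.copy(),
            axis_position=self.axis_position,
            scan_mode=self.scan_mode,
        )
        params.update(kwargs)
        return Geometry(**params)

    def to_dict(self) -> dict:
        """Flat key-value form for the workflow parameter file."""
        return {
            "energy": float(self.energy),
            "pixel_size": float(self.pixel_size),
            "distance": float(self.distance),
            "angles": [float(a) for a in self.angles],
            "axis_position": float(self.axis_position),
            "scan_mode": self.scan_mode.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            energy=d["energy"],
            pixel_size=d["pixel_size"],
            distance=d["distance"],
            angles=np.asarray(d["angles"], dtype=float),
            axis_position=d["axis_position"],
            scan_mode=ScanMode(d["scan_mode"]),
        )


def fresnel_number(feature_size: float, geometry: Geometry) -> float:
    """Fresnel number ``a^2 / (lambda d)`` for a feature of size ``a``.

    Diagnoses the propagation regime: ``N_F >> 1`` is near field (where
    TIE-based retrieval is valid), ``N_F <~ 1`` shows Fresnel fringes.
    Returns :class:`ContactRegime` (an inf float) at zero distance.
    """
    if feature_size <= 0:
        raise ValueError("feature_size must be > 0")
    if geometry.distance == 0:
        return ContactRegime()
    return feature_size**2 / (geometry.wavelength * geometry.distance)


@dataclass
class RefractiveMap:
    """Paired 2-D maps of the refractive-index components of a slice.

    ``delta`` and ``beta`` are the dimensionless decrement and imaginary
    part of ``n = 1 - delta + i beta`` sampled on a square grid of pitch
    ``pixel_size`` (m).
    """

    delta: np.ndarray
    beta: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.delta.shape != self.beta.shape:
            raise ValueError("delta and beta maps must have identical shape")
        if np.any(self.beta < 0):
            raise ValueError("beta must be non-negative everywhere")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.delta.shape


def _as_stack(arr: np.ndarray) -> np.ndarray:
    """Promote a single (H, W) frame to a (1, H, W) stack."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a frame stack, got ndim={arr.ndim}")
    return arr


@dataclass
class ProjectionSet:
    """Raw projection stack with its flat (white) and dark frames.

    ``projections`` is ``(n_proj, height, width)`` in detector counts;
    ``flats_before`` / ``flats_after`` are no-sample beam frames taken at
    the two ends of the scan, ``darks`` no-beam frames.  One projection
    per geometry angle.
    """

    projections: np.ndarray
    flats_before: np.ndarray
    flats_after: np.ndarray
    darks: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.projections = _as_stack(np.asarray(self.projections))
        for name in ("flats_before", "flats_after", "darks"):
            arr = np.asarray(getattr(self, name))
            if arr.size == 0:
                arr = arr.reshape((0,) + self.frame_shape)
            setattr(self, name, _as_stack(arr))
        h, w = self.frame_shape
        for name in ("flats_before", "flats_after", "darks"):
            arr = getattr(self, name)
            if arr.shape[1:] != (h, w):
                raise ValueError(f"{name} frames {arr.shape[1:]} do not match projections {(h, w)}")
        if self.projections.shape[0] != self.geometry.n_angles:
            raise ValueError(
                f"{self.projections.shape[0]} projections but "
                f"{self.geometry.n_angles} angles in the geometry"
            )
        if self.n_flats == 0:
            raise ValueError("at least one flat frame is required")
        if self.darks.shape[0] == 0:
            raise ValueError("at least one dark frame is required")

    @property
    def frame_shape(self) -> tuple:
        return self.projections.shape[1:]

    @property
    def n_proj(self) -> int:
        return self.projections.shape[0]

    @property
    def n_flats(self) -> int:
        return self.flats_before.shape[0] + self.flats_after.shape[0]

    @property
    def flats(self) -> np.ndarray:
        """Before- and after-scan flats pooled, in acquisition order."""
        return np.concatenate([self.flats_before, self.flats_after], axis=0)


@dataclass
class Sinogram:
    """All line integrals of one detector row: an (angle x column) image."""

    values: np.ndarray
    angles: np.ndarray
    axis_position: float
    row_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (n_angles x width)")
        if self.values.shape[0] != self.angles.size:
            raise ValueError("one sinogram row per angle required")
        if self.angles.size > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("sinogram rows must be ordered by increasing angle")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def replace_values(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(values, self.angles.copy(), self.axis_position, self.row_index)


@dataclass
class ReconSlice:
    """A reconstructed square slice with its physical pixel size and quantity."""

    values: np.ndarray
    pixel_size: float
    quantity: SliceQuantity = SliceQuantity.ATTENUATION_COEFFICIENT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.quantity = SliceQuantity(self.quantity)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("reconstructed slice must be square")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
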