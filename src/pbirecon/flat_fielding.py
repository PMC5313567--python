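"""Conventional and dynamic (eigen-flat-field) projection normalisation.

Conventional flat fielding divides each dark-subtracted projection by the
dark-subtracted *average* flat frame.  When the beam profile drifts during
the scan (source or monochromator instability) the average flat is wrong
for most projections; dynamic flat fielding models the drift with the
principal components of the collected flat frames ("eigen flat fields")
and fits, per projection, the linear combination of components that best
explains the beam seen by that projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ProjectionSet

__all__ = [
    "EigenFlatBasis",
    "conventional_flat_field",
    "compute_eigen_flats",
    "dynamic_flat_field",
    "flat_field_stack",
]

log = logging.getLogger(__name__)

#: relative floor applied to the flat-minus-dark denominator
DENOM_EPS_REL = 1.0e-6
#: normalised intensities are clipped to [0, CLIP_MAX]
CLIP_MAX = 10.0


@dataclass
class EigenFlatBasis:
    """Mean flat/dark plus the principal components of the flat set.

    ``components`` is a stack of eigen flat images with unit L2 norm,
    ordered by decreasing ``explained_variance`` (fractions of the total
    flat-set variance, summing to <= 1).
    """

    mean_flat: np.ndarray
    mean_dark: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean_flat = np.asarray(self.mean_flat, dtype=float)
        self.mean_dark = np.asarray(self.mean_dark, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.components.size:
            flat = self.components.reshape(self.n_components, -1)
            gram = flat @ flat.T
            off = gram - np.diag(np.diag(gram))
            if np.max(np.abs(off)) > 1.0e-8:
                raise ValueError("eigen flat components must be mutually orthogonal")
            if np.any(np.diff(self.explained_variance) > 1.0e-12):
                raise ValueError("explained_variance must be non-increasing")
            if self.explained_variance.sum() > 1.0 + 1.0e-9:
                raise ValueError("explained variance fractions must sum to <= 1")

    @property
    def n_components(self) -> int:
        return self.components.shape[0] if self.components.ndim == 3 else 0


def _clamp_denominator(denom: np.ndarray) -> np.ndarray:
    floor = DENOM_EPS_REL * float(np.max(denom)) if np.max(denom) > 0 else DENOM_EPS_REL
    return np.maximum(denom, floor)


def conventional_flat_field(
    projection: np.ndarray,
    mean_flat: np.ndarray,
    mean_dark: np.ndarray,
    clip_max: float = CLIP_MAX,
) -> np.ndarray:
    """Normalise a projection: ``N = (P - D) / (F - D)``.

    The denominator is clamped below at a small fraction of its maximum
    and the result clipped to ``[0, clip_max]`` so the downstream
    logarithm of the phase-retrieval step never sees non-positive input.
    Raises if the flats are not above the darks over >1% of pixels.
    """
    projection = np.asarray(projection, dtype=float)
    mean_flat = np.asarray(mean_flat, dtype=float)
    mean_dark = np.asarray(mean_dark, dtype=float)
    if projection.shape != mean_flat.shape or projection.shape != mean_dark.shape:
        raise ValueError("projection, flat and dark shapes must match")
    denom = mean_flat - mean_dark
    bad = np.count_nonzero(denom <= 0)
    if bad > 0.01 * denom.size:
        raise ValueError(
            f"flat field not above dark over {bad / denom.size:.1%} of pixels: bad flats"
        )
    out = (projection - mean_dark) / _clamp_denominator(denom)
    return np.clip(out, 0.0, clip_max)


def compute_eigen_flats(
    flats: np.ndarray, darks: np.ndarray, n_components: int
) -> EigenFlatBasis:
    """Principal components of the dark-subtracted flat frames.

    The flats are dark-subtracted, mean-centred and decomposed by SVD;
    the top ``n_components`` right-singular images (unit L2 norm) are kept
    together with their explained-variance fractions.  Works from as few
    as two flats (one drift mode), although the drift subspace is
    estimated better from dozens or hundreds of frames.  Components whose
    singular value is numerically zero (identical flats) are dropped.
    """
    flats = np.asarray(flats, dtype=float)
    darks = np.asarray(darks, dtype=float)
    if flats.ndim == 2:
        flats = flats[None]
    if darks.ndim == 2:
        darks = darks[None]
    n_flats = flats.shape[0]
    if n_flats < 2:
        raise ValueError("at least two flat frames are required for the PCA")
    if not (0 < n_components < n_flats):
        raise ValueError("n_components must satisfy 0 < n_components < n_flats")
    mean_dark = darks.mean(axis=0)
    corrected = flats - mean_dark
    mean_flat = flats.mean(axis=0)
    centred = (corrected - corrected.mean(axis=0)).reshape(n_flats, -1)
    # SVD of the (n_flats x n_pixels) matrix: rows of Vt are eigen images
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(svals**2))
    tol = max(svals[0], 1.0) * 1.0e-12 if svals.size else 0.0
    keep = min(n_components, int(np.count_nonzero(svals > tol)))
    shape = flats.shape[1:]
    if keep == 0 or total == 0.0:
        return EigenFlatBasis(
            mean_flat=mean_flat,
            mean_dark=mean_dark,
            components=np.empty((0,) + shape),
            explained_variance=np.empty(0),
        )
    components = vt[:keep].reshape((keep,) + shape)
    explained = (svals[:keep] ** 2) / total
    return EigenFlatBasis(
        mean_flat=mean_flat,
        mean_dark=mean_dark,
        components=components,
        explained_variance=explained,
    )


def dynamic_flat_field(
    projection: np.ndarray,
    basis: EigenFlatBasis,
    estimation_region: np.ndarray | None = None,
    clip_max: float = CLIP_MAX,
) -> np.ndarray:
    """Normalise one projection against a per-frame synthesised flat.

    The residual ``P - D - (F - D)`` is fitted, by linear least squares
    over ``estimation_region`` (a boolean mask; default the whole frame,
    in practice air-only columns work best), onto the eigen flat images;
    the projection is then divided by the synthesised flat
    ``(F - D) + sum_k w_k E_k``.  With an empty basis, or if the normal
    equations are singular, this reduces to conventional flat fielding
    (the fallback is logged).
    """
    projection = np.asarray(projection, dtype=float)
    if basis.n_components == 0:
        return conventional_flat_field(
            projection, basis.mean_flat, basis.mean_dark, clip_max=clip_max
        )
    if estimation_region is None:
        region = np.ones(projection.shape, dtype=bool)
    else:
        region = np.asarray(estimation_region, dtype=bool)
        if region.shape != projection.shape:
            raise ValueError("estimation_region mask must match the projection shape")
    residual = projection - basis.mean_dark - (basis.mean_flat - basis.mean_dark)
    A = basis.components.reshape(basis.n_components, -1)[:, region.ravel()].T
    b = residual.ravel()[region.ravel()]
    try:
        weights, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not np.all(np.isfinite(weights)):
            raise np.linalg.LinAlgError("non-finite weights")
    except np.linalg.LinAlgError:
        log.warning("dynamic flat fielding: singular fit, falling back to conventional")
        warnings.warn(
            "dynamic flat fielding fell back to conventional (singular fit)",
            stacklevel=2,
        )
        return conventional_flat_field(
            projection, basis.mean_flat, basis.mean_dark, clip_max=clip_max
        )
    synthetic = basis.mean_flat - basis.mean_dark + np.tensordot(
        weights, basis.components, axes=(0, 0)
    )
    out = (projection - basis.mean_dark) / _clamp_denominator(synthetic)
    return np.clip(out, 0.0, clip_max)


def flat_field_stack(
    ps: ProjectionSet,
    method: str = "conventional",
    n_components: int = 2,
    estimation_region: np.ndarray | None = None,
    clip_max: float = CLIP_MAX,
) -> np.ndarray:
    """Flat-field every projection of a set; returns the normalised stack.

    ``method='dynamic'`` builds the eigen-flat basis from the pooled
    before/after flats (capped at n_flats - 1 components) and corrects
    each projection individually; ``'conventional'`` uses the average
    flat for all of them.
    """
    flats = ps.flats
    mean_dark = ps.darks.mean(axis=0)
    if method == "conventional":
        mean_flat = flats.mean(axis=0)
        return np.stack(
            [
                conventional_flat_field(p, mean_flat, mean_dark, clip_max=clip_max)
                for p in ps.projections
            ]
        )
    if method == "dynamic":
        n_comp = min(n_components, flats.shape[0] - 1)
        if n_comp < 1:
            raise ValueError("dynamic flat fielding needs at least two flat frames")
        basis = compute_eigen_flats(flats, ps.darks, n_comp)
        if isinstance(estimation_region, str) and estimation_region == "auto":
            conv = np.stack(
                [
                    conventional_flat_field(
                        p, flats.mean(axis=0), mean_dark, clip_max=clip_max
                    )
                    for p in ps.projections
                ]
            )
            estimation_region = detect_air_region(conv)
        return np.stack(
            [
                dynamic_flat_field(
                    p, basis, estimation_region=estimation_region, clip_max=clip_max
                )
                for p in ps.projections
            ]
        )
    raise ValueError(f"unknown flat-fielding method {method!r}")


def detect_air_region(
    normalized_stack: np.ndarray, threshold: float = 0.95, min_fraction: float = 0.02
) -> np.ndarray | None:
    """Air (object-free) pixels of a scan, from a normalised first pass.

    A pixel counts as air when its median normalised intensity over all
    projections stays above ``threshold`` (the beam is never attenuated
    there).  Returns a boolean mask, or None (meaning: use the whole
    frame) when fewer than ``min_fraction`` of pixels qualify.  Fitting
    the dynamic flat-field weights on air only keeps object structure
    from being absorbed into the synthesised flat.
    """
    median = np.median(normalized_stack, axis=0)
    mask = median > threshold
    if mask.mean() < min_fraction:
        return None
    return mask
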