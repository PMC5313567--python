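"""Parallel-beam tomographic inversion: filtered back projection and SIRT.

Both algorithms share one discrete projector pair: a pixel-driven forward
model that splats each pixel onto the two nearest detector bins with
linear weights (approximating the line integral as value * pixel_size),
and its exact transpose, back projection with linear interpolation at the
projected pixel position.  FBP uses the transpose after ramp filtering;
SIRT iterates x <- x + C A^T R (b - A x) with inverse row/column sum
weighting, so the matched pair guarantees a non-expansive update.

Conventions: a pixel (i, j) of the N x N slice sits at
(x, y) = (j - (N-1)/2, i - (N-1)/2) pixels relative to the rotation axis,
and projects at angle theta onto detector position
p = x cos(theta) + y sin(theta) + axis_position (fractional 0-based
column).  The FBP output is scaled by pi / n_angles times 1/pixel_size
(with the plain |f| ramp in cycles/pixel), so a sinogram of line
integrals in [quantity * m] reconstructs the quantity itself.
"""

from __future__ import annotations

import numpy as np

from .core import Geometry, ReconSlice, ScanMode, Sinogram, SliceQuantity

__all__ = ["fbp", "sirt", "radon_forward", "FILTERS"]

FILTERS = ("ramlak", "shepp_logan", "hann")


def _check_span(angles: np.ndarray) -> None:
    span = angles[-1] - angles[0]
    steps = np.diff(angles)
    eps = 2.0 * float(np.median(steps)) if steps.size else 0.0
    if span < 180.0 - eps:
        raise ValueError(
            f"angle span {span:.2f} deg < 180 deg: insufficient for reconstruction"
        )


def _pixel_offsets(n: int) -> np.ndarray:
    return np.arange(n, dtype=float) - (n - 1) / 2.0


def _project_one(
    img: np.ndarray, cos_t: float, sin_t: float, axis: float, width: int
) -> np.ndarray:
    """Forward-project one angle: splat pixels onto detector bins."""
    n = img.shape[0]
    off = _pixel_offsets(n)
    p = cos_t * off[None, :] + sin_t * off[:, None] + axis
    k0 = np.floor(p).astype(int)
    w = p - k0
    out = np.zeros(width)
    for k, wgt in ((k0, (1.0 - w)), (k0 + 1, w)):
        valid = (k >= 0) & (k < width)
        out += np.bincount(
            k[valid], weights=(img * wgt)[valid], minlength=width
        )[:width]
    return out


def _backproject_one(
    q: np.ndarray, cos_t: float, sin_t: float, axis: float, n: int
) -> np.ndarray:
    """Transpose of :func:`_project_one`: interpolate q at pixel positions."""
    off = _pixel_offsets(n)
    p = cos_t * off[None, :] + sin_t * off[:, None] + axis
    k0 = np.floor(p).astype(int)
    w = p - k0
    width = q.shape[0]
    out = np.zeros((n, n))
    for k, wgt in ((k0, (1.0 - w)), (k0 + 1, w)):
        valid = (k >= 0) & (k < width)
        out[valid] += wgt[valid] * q[k[valid]]
    return out


def radon_forward(
    slice_: ReconSlice | np.ndarray,
    angles: np.ndarray,
    axis_position: float | None = None,
    pixel_size: float | None = None,
    width: int | None = None,
) -> Sinogram:
    """Discrete line-integral projection of a square slice.

    The forward model matched to the SIRT/FBP back projector: each pixel
    contributes ``value * pixel_size`` split linearly between the two
    nearest detector bins.  Output units are [slice quantity] * m.
    """
    if isinstance(slice_, ReconSlice):
        img = np.asarray(slice_.values, dtype=float)
        pixel_size = slice_.pixel_size if pixel_size is None else pixel_size
    else:
        img = np.asarray(slice_, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare array")
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("slice must be square")
    n = img.shape[0]
    if width is None:
        width = n
    if axis_position is None:
        axis_position = (width - 1) / 2.0
    angles = np.asarray(angles, dtype=float)
    th = np.deg2rad(angles)
    values = np.empty((angles.size, width))
    for i, t in enumerate(th):
        values[i] = _project_one(img, np.cos(t), np.sin(t), axis_position, width)
    return Sinogram(
        values=values * pixel_size, angles=angles, axis_position=axis_position
    )


def _ramp_filter(width_padded: int, filter_name: str) -> np.ndarray:
    f = np.fft.rfftfreq(width_padded)  # cycles/pixel, up to 0.5
    # band-limited ramp: DFT of the discrete ramp kernel
    # (1/4 at 0, -1/(pi n)^2 at odd n), which tends to |f| but avoids the
    # DC deficit of sampling |f| directly
    n = np.concatenate(
        [np.arange(0, width_padded // 2 + 1), np.arange(width_padded // 2 - 1, 0, -1)]
    )
    kernel = np.zeros(width_padded)
    kernel[0] = 0.25
    odd = n % 2 == 1
    kernel[odd] = -1.0 / (np.pi * n[odd]) ** 2
    ramp = 2.0 * np.real(np.fft.rfft(kernel))
    if filter_name == "ramlak":
        window = np.ones_like(f)
    elif filter_name == "shepp_logan":
        window = np.sinc(f)  # sin(pi f)/(pi f), =1 at f=0
    elif filter_name == "hann":
        window = 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    else:
        raise ValueError(f"unknown FBP filter {filter_name!r}; choose from {FILTERS}")
    return ramp * window


def fbp(
    sino: Sinogram,
    filter_name: str = "shepp_logan",
    axis_position: float | None = None,
    pixel_size: float = 1.0,
    output_size: int | None = None,
    quantity: SliceQuantity = SliceQuantity.ATTENUATION_COEFFICIENT,
    circle: bool = True,
) -> ReconSlice:
    """Filtered back projection of a 180-degree parallel-beam sinogram.

    Rows are zero-padded to the next power of two >= 2x width, filtered
    in the Fourier domain by |f| times the chosen apodisation window and
    back-projected with linear interpolation about ``axis_position``.
    The output is scaled so that a sinogram of physical line integrals
    (units [q]*m, detector pitch ``pixel_size`` m) reconstructs the
    quantity q itself.  ``circle=True`` zeroes pixels outside the
    inscribed circle (outside the reliably sampled region).
    """
    values = sino.values
    if not np.all(np.isfinite(values)):
        raise ValueError("sinogram contains non-finite values")
    _check_span(sino.angles)
    axis = float(sino.axis_position if axis_position is None else axis_position)
    n_ang, width = values.shape
    if not (0.0 <= axis <= width - 1):
        raise ValueError("rotation axis lies outside the detector")
    n_out = width if output_size is None else int(output_size)
    padded = int(2 ** np.ceil(np.log2(max(2 * width, 64))))
    filt = _ramp_filter(padded, filter_name)
    spec = np.fft.rfft(values, padded, axis=1) * filt[None, :]
    filtered = np.fft.irfft(spec, padded, axis=1)[:, :width]
    th = np.deg2rad(sino.angles)
    out = np.zeros((n_out, n_out))
    for i, t in enumerate(th):
        out += _backproject_one(filtered[i], np.cos(t), np.sin(t), axis, n_out)
    out *= np.pi / (2.0 * n_ang) / pixel_size
    if circle:
        off = _pixel_offsets(n_out)
        mask = off[None, :] ** 2 + off[:, None] ** 2 <= ((n_out - 1) / 2.0) ** 2
        out = np.where(mask, out, 0.0)
    return ReconSlice(values=out, pixel_size=pixel_size, quantity=quantity)


def sirt(
    sino: Sinogram,
    n_iterations: int = 100,
    nonneg: bool = False,
    axis_position: float | None = None,
    pixel_size: float = 1.0,
    output_size: int | None = None,
    quantity: SliceQuantity = SliceQuantity.ATTENUATION_COEFFICIENT,
) -> tuple[ReconSlice, np.ndarray]:
    """Simultaneous iterative reconstruction (SIRT) with the matched pair.

    Iterates ``x <- x + C A^T R (b - A x)`` from zero, with R and C the
    inverse row and column sums of the system matrix A (the linear
    interpolation projector of :func:`radon_forward`).  ``nonneg`` clamps
    negatives after every update.  Returns the slice and the per-iteration
    data residual norms; raises if the residual grows three iterations in
    a row (divergence).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    values = sino.values
    if not np.all(np.isfinite(values)):
        raise ValueError("sinogram contains non-finite values")
    _check_span(sino.angles)
    axis = float(sino.axis_position if axis_position is None else axis_position)
    n_ang, width = values.shape
    n_out = width if output_size is None else int(output_size)
    th = np.deg2rad(sino.angles)
    cos_t, sin_t = np.cos(th), np.sin(th)

    def forward(img: np.ndarray) -> np.ndarray:
        out = np.empty((n_ang, width))
        for i in range(n_ang):
            out[i] = _project_one(img, cos_t[i], sin_t[i], axis, width)
        return out * pixel_size

    def backward(res: np.ndarray) -> np.ndarray:
        out = np.zeros((n_out, n_out))
        for i in range(n_ang):
            out += _backproject_one(res[i], cos_t[i], sin_t[i], axis, n_out)
        return out * pixel_size

    row_sums = forward(np.ones((n_out, n_out)))
    col_sums = backward(np.ones((n_ang, width)))
    R = np.where(row_sums > 0, 1.0 / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    C = np.where(col_sums > 0, 1.0 / np.where(col_sums > 0, col_sums, 1.0), 0.0)

    x = np.zeros((n_out, n_out))
    residuals = np.empty(n_iterations)
    growth = 0
    for it in range(n_iterations):
        res = values - forward(x)
        residuals[it] = float(np.linalg.norm(res))
        x = x + C * backward(R * res)
        if nonneg:
            np.maximum(x, 0.0, out=x)
        if it > 0 and residuals[it] > residuals[it - 1] * (1.0 + 1.0e-9):
            growth += 1
            if growth >= 3:
                raise RuntimeError(
                    f"SIRT diverging: residual grew 3 consecutive iterations "
                    f"(last norms {residuals[max(0, it - 3):it + 1]})"
                )
        else:
            growth = 0
    return ReconSlice(values=x, pixel_size=pixel_size, quantity=quantity), residuals
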