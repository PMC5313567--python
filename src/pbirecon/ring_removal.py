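"""Sinogram de-striping filters for ring-artifact compensation.

Fixed-pattern detector gain errors (scintillator bright spots, column
gain mismatch) survive flat fielding as *angle-constant stripes* in the
sinogram and become concentric rings in the reconstructed slice.  Both
filters here suppress the stripes in the sinogram domain and may be
applied before or after (or both around) phase retrieval.

``raven_filter`` is a Fourier-domain approach: stripes live in the rows
of lowest angular frequency of the 2-D sinogram spectrum, where they are
broadband in the detector frequency; a Butterworth low-pass applied to
those rows removes the sharp stripe content while keeping the smooth
object trend.  The generalisation over the classic single-row (zero
angular frequency) filter is the number of low angular-frequency lines
processed, ``n_angular_lines``.

``column_normalization_filter`` is a simple representative of the
statistical de-striper family: each detector column is rescaled so that
its angular mean follows a smoothed version of the column-mean profile.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import ReconSlice, Sinogram

__all__ = [
    "raven_filter",
    "column_normalization_filter",
    "ring_energy",
]


def raven_filter(
    sino: Sinogram,
    u0: float = 0.05,
    butterworth_order: int = 4,
    n_angular_lines: int = 2,
) -> Sinogram:
    """Fourier low-pass de-striping of the low angular-frequency lines.

    Parameters
    ----------
    u0 : float
        Butterworth cut-off in cycles/pixel along the detector axis,
        in (0, 0.5).
    butterworth_order : int
        Filter order (>= 1); the low-pass is
        ``H(u) = 1 / (1 + (u/u0)^(2 order))``, so ``H(0) = 1`` and the
        sinogram mean is preserved.
    n_angular_lines : int
        Number of angular-frequency lines |m| < n_angular_lines to
        process (1 reproduces the classic filter acting only on the
        angle-average line).
    """
    if not (0.0 < u0 < 0.5):
        raise ValueError("u0 must lie in (0, 0.5) cycles/pixel")
    if butterworth_order < 1:
        raise ValueError("butterworth_order must be >= 1")
    if n_angular_lines < 1:
        raise ValueError("n_angular_lines must be >= 1")
    values = sino.values
    n_ang, width = values.shape
    spectrum = np.fft.fft2(values)
    u = np.fft.fftfreq(width)  # detector frequency, cycles/pixel
    lowpass = 1.0 / (1.0 + (np.abs(u) / u0) ** (2 * butterworth_order))
    m = np.fft.fftfreq(n_ang, d=1.0 / n_ang)  # integer angular frequencies
    rows = np.abs(m) < n_angular_lines  # Nyquist row (m = -n/2) only if within
    spectrum[rows] *= lowpass[None, :]
    filtered = np.fft.ifft2(spectrum)
    resid = np.max(np.abs(filtered.imag))
    scale = np.ptp(values)
    if scale > 0 and resid > 1.0e-8 * scale:
        raise FloatingPointError("unexpected imaginary residue after de-striping")
    return sino.replace_values(filtered.real)


def column_normalization_filter(sino: Sinogram, smoothing_width: int = 21) -> Sinogram:
    """Rescale each detector column onto the smoothed column-mean trend.

    The per-column angular mean ``c(x)`` is smoothed by a moving average
    of ``smoothing_width`` pixels (odd, >= 3) into the trend ``c_hat(x)``;
    each column is divided by ``c(x) / c_hat(x)``.  Stripes (sharp
    deviations of ``c``) are removed, slowly varying object structure is
    passed through.  Requires strictly positive column means, i.e. a
    flat-fielded sinogram.
    """
    if smoothing_width < 3 or smoothing_width % 2 == 0:
        raise ValueError("smoothing_width must be odd and >= 3")
    c = sino.values.mean(axis=0)
    if np.any(c <= 0):
        raise ValueError(
            "non-positive column means: the filter must run after flat fielding"
        )
    c_hat = uniform_filter1d(c, size=smoothing_width, mode="nearest")
    return sino.replace_values(sino.values * (c_hat / c)[None, :])


def ring_energy(
    slice_: ReconSlice | np.ndarray,
    center: tuple[float, float] | None = None,
    reference: ReconSlice | np.ndarray | None = None,
) -> float:
    """Angular-variance statistic quantifying ring artifacts in a slice.

    For every integer radius about ``center`` the variance of the pixels
    on that circle is computed; the statistic is the mean of those
    variances over radii.  Rings are angle-constant, radius-dependent
    errors, so they inflate nothing *but* this statistic; a radially
    symmetric image scores ~0 beyond discretisation.  If a ``reference``
    image is given (ground truth or a ring-free reconstruction), its
    statistic is subtracted so that genuine angular structure of the
    object does not count as ring energy.
    """
    img = slice_.values if isinstance(slice_, ReconSlice) else np.asarray(slice_)
    stat = _angular_variance(img, center)
    if reference is not None:
        ref = reference.values if isinstance(reference, ReconSlice) else np.asarray(reference)
        stat -= _angular_variance(ref, center)
    return float(stat)


def _angular_variance(img: np.ndarray, center: tuple[float, float] | None) -> float:
    n, m = img.shape
    if center is None:
        center = ((n - 1) / 2.0, (m - 1) / 2.0)
    yy, xx = np.indices(img.shape)
    r = np.hypot(yy - center[0], xx - center[1])
    radius = np.round(r).astype(int)
    rmax = min(n, m) // 2
    keep = radius <= rmax
    radius, vals = radius[keep], img[keep]
    counts = np.bincount(radius, minlength=rmax + 1).astype(float)
    sums = np.bincount(radius, weights=vals, minlength=rmax + 1)
    sq = np.bincount(radius, weights=vals**2, minlength=rmax + 1)
    ok = counts > 1
    var = np.zeros_like(sums)
    var[ok] = sq[ok] / counts[ok] - (sums[ok] / counts[ok]) ** 2
    return float(var[ok].mean()) if np.any(ok) else 0.0
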