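"""Rotation-axis (center-of-rotation) estimation and extended-FOV stitching.

In a parallel-beam scan a projection at angle theta+180 degrees is the
horizontal mirror image of the one at theta about the rotation-axis
column.  Cross-correlating a projection with the mirrored opposite
projection therefore locates the axis; in an offset-axis 360-degree scan
("half acquisition") the same relation lets opposite sinogram rows be
stitched into 180-degree rows of almost twice the detector width.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from .core import ProjectionSet, ScanMode, Sinogram

__all__ = [
    "AxisEstimate",
    "estimate_axis_position",
    "stitch_half_acquisition",
    "extract_sinogram",
    "LowConfidenceAxisWarning",
]

#: normalised correlation peaks below this are flagged low-confidence
MIN_PEAK_CORRELATION = 0.2


class LowConfidenceAxisWarning(UserWarning):
    """The axis correlation peak is weak; the estimate may be unreliable."""


class AxisEstimate(NamedTuple):
    """Axis column estimate with the correlation score backing it."""

    position: float
    peak_correlation: float

    @property
    def low_confidence(self) -> bool:
        return self.peak_correlation < MIN_PEAK_CORRELATION


def estimate_axis_position(
    proj_0deg: np.ndarray, proj_180deg: np.ndarray
) -> AxisEstimate:
    """Locate the rotation-axis column from an opposite projection pair.

    Mirrors ``proj_180deg`` horizontally, finds the shift ``s`` that
    maximises the normalised cross-correlation with ``proj_0deg``
    (integer peak plus parabolic sub-pixel refinement) and returns
    ``axis = (W - 1) / 2 + s / 2``.  A peak correlation below 0.2 (e.g.
    featureless images) attaches a low-confidence warning to the result.
    """
    p0 = np.asarray(proj_0deg, dtype=float)
    p180 = np.asarray(proj_180deg, dtype=float)
    if p0.ndim == 1:
        p0, p180 = p0[None], p180[None]
    if p0.shape != p180.shape:
        raise ValueError("the two projections must have the same shape")
    h, w = p0.shape
    shifts, ncc = _ncc_curve(p0, p180)
    s, peak = _refine_peak(shifts, ncc)

    estimate = AxisEstimate(position=(w - 1) / 2.0 + s / 2.0, peak_correlation=peak)
    if estimate.low_confidence:
        warnings.warn(
            f"axis estimate has low confidence (peak correlation {peak:.3f} < "
            f"{MIN_PEAK_CORRELATION})",
            LowConfidenceAxisWarning,
            stacklevel=2,
        )
    return estimate


def _ncc_curve(p0: np.ndarray, p180: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Windowed NCC of a projection against the mirrored opposite one.

    Only the overlap window of the two views is mirror-consistent (in an
    offset-axis scan features outside it have no counterpart), so the NCC
    is evaluated over the overlapping columns of each candidate shift.
    """
    w = p0.shape[1]
    mirrored = p180[:, ::-1]
    min_overlap = max(8, w // 8)
    shifts = np.arange(-(w - min_overlap), w - min_overlap + 1)
    ncc = np.zeros(shifts.size)
    for idx, s_int in enumerate(shifts):
        if s_int >= 0:
            x, y = p0[:, s_int:], mirrored[:, : w - s_int]
        else:
            x, y = p0[:, : w + s_int], mirrored[:, -s_int:]
        xc = x - x.mean()
        yc = y - y.mean()
        norm = np.linalg.norm(xc) * np.linalg.norm(yc)
        ncc[idx] = float(np.sum(xc * yc) / norm) if norm > 0 else 0.0
    return shifts, ncc


def _refine_peak(shifts: np.ndarray, ncc: np.ndarray) -> tuple[float, float]:
    k = int(np.argmax(ncc))
    peak = float(ncc[k])
    s = float(shifts[k])
    if 0 < k < ncc.size - 1:
        c_m, c_0, c_p = ncc[k - 1], ncc[k], ncc[k + 1]
        denom = c_m - 2 * c_0 + c_p
        if denom < 0:
            s += 0.5 * (c_m - c_p) / denom
    return s, peak


def estimate_axis_from_scan(
    normalized_stack: np.ndarray, angles: np.ndarray, n_pairs: int = 8
) -> AxisEstimate:
    """Axis estimate pooled over several theta / theta+180 pairs of a scan.

    Averaging the windowed NCC curves of up to ``n_pairs`` opposite
    projection pairs suppresses the spurious secondary peaks a single
    truncated pair can show.  Falls back to the 0/180 pair when the scan
    covers less than 360 degrees.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.size
    span = angles[-1] - angles[0]
    if span < 270.0:  # a 180-degree scan has exactly one usable pair
        j = int(np.argmin(np.abs(angles - (angles[0] + 180.0))))
        return estimate_axis_position(normalized_stack[0], normalized_stack[j])
    n_half = n // 2
    picks = np.unique(np.linspace(0, n_half - 1, min(n_pairs, n_half)).astype(int))
    curves = []
    for i in picks:
        target = angles[i] + 180.0
        j = int(np.argmin(np.abs(angles - target)))
        shifts, ncc = _ncc_curve(
            np.atleast_2d(normalized_stack[i]), np.atleast_2d(normalized_stack[j])
        )
        curves.append(ncc)
    mean_curve = np.mean(curves, axis=0)
    s, peak = _refine_peak(shifts, mean_curve)
    w = normalized_stack.shape[-1]
    estimate = AxisEstimate(position=(w - 1) / 2.0 + s / 2.0, peak_correlation=peak)
    if estimate.low_confidence:
        warnings.warn(
            f"axis estimate has low confidence (mean peak correlation {peak:.3f})",
            LowConfidenceAxisWarning,
            stacklevel=2,
        )
    return estimate


def _stitch_rows(
    first: np.ndarray, second: np.ndarray, axis_position: float, blend: str
) -> np.ndarray:
    """Stitch rows(theta) with rows(theta+180) about an axis in the right half."""
    n, w = first.shape
    a = float(axis_position)
    w_out = int(round(2 * a + 1))
    v = 2 * w - w_out  # overlap width in pixels
    j = np.arange(w_out, dtype=float)
    s = j - (w_out - 1) / 2.0  # signed offset from the stitched-frame axis
    col_first = s + a  # where view theta sees offset s
    col_second = a - s  # where the mirrored view theta+180 sees it
    in_first = (col_first >= 0) & (col_first <= w - 1)
    in_second = (col_second >= 0) & (col_second <= w - 1)
    cols = np.arange(w, dtype=float)
    out = np.zeros((n, w_out))
    weight_first = np.zeros(w_out)
    both = in_first & in_second
    only_first = in_first & ~in_second
    weight_first[only_first] = 1.0
    if np.any(both):
        lo, hi = col_first[both].min(), col_first[both].max()
        if blend == "ramp":
            # 1 at the deep end of view theta, 0 where only theta+180 remains
            weight_first[both] = (
                (hi - col_first[both]) / (hi - lo) if hi > lo else 0.5
            )
        elif blend == "cosine":
            x = (hi - col_first[both]) / (hi - lo) if hi > lo else 0.5
            weight_first[both] = 0.5 - 0.5 * np.cos(np.pi * x)
        elif blend == "cut":
            weight_first[both] = (col_first[both] <= (lo + hi) / 2).astype(float)
        else:
            raise ValueError(f"unknown overlap blend {blend!r}")
    covered = in_first | in_second
    for i in range(n):
        row_a = np.interp(col_first[in_first], cols, first[i])
        row_b = np.interp(col_second[in_second], cols, second[i])
        acc = np.zeros(w_out)
        acc[in_first] += weight_first[in_first] * row_a
        acc[in_second] += (1.0 - weight_first)[in_second] * row_b
        if not covered.all():
            # sub-pixel uncovered margin when the axis is fractional:
            # extend with the nearest covered value
            acc[~covered] = np.interp(
                j[~covered], j[covered], acc[covered]
            )
        out[i] = acc
    return out


def stitch_half_acquisition(
    sino_360: Sinogram, axis_position: float | None = None, blend: str = "ramp"
) -> Sinogram:
    """Fold an offset-axis 360-degree sinogram into a wide 180-degree one.

    Pairs row theta with the mirrored row theta+180 and joins them about
    the rotation axis; the output width is ``round(2 a + 1)`` for an axis
    at column ``a`` in the right half of the detector (mirror-symmetric
    formula on the left half), with the overlap region of width
    ``2 W - W'`` blended by a linear ramp (or ``cosine`` / hard ``cut``).
    Output rows carry the first half of the input angles and the axis sits
    at the centre column ``(W' - 1) / 2``.
    """
    if sino_360.n_angles % 2 != 0:
        raise ValueError("an even number of angle rows is required to pair theta with theta+180")
    n_half = sino_360.n_angles // 2
    angles = sino_360.angles
    if not np.allclose(angles[n_half:] - angles[:n_half], 180.0, atol=1.0e-6):
        raise ValueError("rows theta and theta+180 must be present for every theta")
    a = float(sino_360.axis_position if axis_position is None else axis_position)
    w = sino_360.width
    if not (0.0 <= a <= w - 1):
        raise ValueError("rotation axis must lie inside the detector")
    centre = (w - 1) / 2.0
    flipped = not (a >= centre)
    values = sino_360.values
    if flipped:
        # mirror the detector so the axis lands in the right half, stitch,
        # then mirror the result back
        values = values[:, ::-1]
        a = (w - 1) - a
    w_out = int(round(2 * a + 1))
    if 2 * w - w_out >= w:
        raise ValueError(
            "degenerate overlap: the axis is at the detector centre; "
            "use scan_mode half_turn_180 instead of stitching"
        )
    # row theta+180 at detector column c sees the signed offset a - c in the
    # theta frame, so _stitch_rows samples the raw opposite rows at a - s
    stitched = _stitch_rows(values[:n_half], values[n_half:], a, blend)
    if flipped:
        stitched = stitched[:, ::-1]
    return Sinogram(
        values=stitched,
        angles=angles[:n_half].copy(),
        axis_position=(w_out - 1) / 2.0,
        row_index=sino_360.row_index,
    )


def extract_sinogram(ps: ProjectionSet, row_index: int, stack: np.ndarray | None = None) -> Sinogram:
    """One detector row across all projections, in angle order.

    ``stack`` optionally substitutes a processed (e.g. flat-fielded)
    stack for the raw projections; values are taken bit-exactly.
    """
    data = ps.projections if stack is None else np.asarray(stack)
    if not (0 <= row_index < data.shape[1]):
        raise IndexError(f"row {row_index} outside detector height {data.shape[1]}")
    return Sinogram(
        values=data[:, row_index, :].astype(float),
        angles=ps.geometry.angles.copy(),
        axis_position=ps.geometry.axis_position,
        row_index=row_index,
    )
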