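"""Rigid registration of nodule segmentations to the reference mask.

Segmentations from differently oriented/positioned acquisitions are compared
on a common isotropic grid (default 0.14 mm): each mask is upsampled with
cubic interpolation and re-binarised at 0.5, rotated about its centroid
(angles supplied, or found by a bounded search maximising Dice), and shifted
by the integer translation that maximises the 2-D cross-correlation of the
axial mid-slices (through-plane shift from 1-D correlation of per-slice
voxel counts — an extension, since mid-slice correlation alone cannot fix
z). A final guard keeps the transformed mask only if it does not lower the
Dice against the reference, so registration never hurts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .geometry import BinaryMask
from .imaging import resample
from .geometry import ImageVolume
from .stats import dice_coefficient

__all__ = [
    "RegistrationParams",
    "upsample_isotropic",
    "rotate_mask",
    "align_translation_xcorr",
    "register_to_reference",
]

log = logging.getLogger(__name__)

DEFAULT_ISO_MM = 0.14


@dataclass(frozen=True)
class RegistrationParams:
    """Rigid transform: rotations about x, y, z (deg) and an integer shift."""

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift_vox: tuple[int, int, int] = (0, 0, 0)


def _is_isotropic(mask: BinaryMask, tol: float = 1e-6) -> bool:
    return max(mask.spacing) - min(mask.spacing) < tol


def upsample_isotropic(mask: BinaryMask, target_mm: float = DEFAULT_ISO_MM) -> BinaryMask:
    """Cubic interpolation of the 0/1 field to an isotropic grid, cut at 0.5."""
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    as_float = ImageVolume(
        mask.values.astype(np.float32), mask.spacing, mask.origin
    )
    up = resample(as_float, (target_mm,) * 3, method="cubic")
    return BinaryMask(up.values > 0.5, up.spacing, up.origin)


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
    )
    ry = np.array(
        [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
    )
    rz = np.array(
        [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
    )
    return rz @ ry @ rx


def rotate_mask(mask: BinaryMask, angles_deg) -> BinaryMask:
    """Rigid rotation about the mask centroid (linear interp, cut at 0.5).

    Requires an isotropic grid so index-space rotation equals physical
    rotation.
    """
    if not _is_isotropic(mask):
        raise ValueError("rotate_mask requires an isotropic grid")
    if np.allclose(angles_deg, 0.0):
        return mask.with_values(mask.values.copy())
    if not mask.values.any():
        return mask.with_values(mask.values.copy())
    centroid = np.array(ndimage.center_of_mass(mask.values))
    rot = _rotation_matrix(angles_deg)
    # affine_transform maps output coords -> input coords with rot^-1
    inv = rot.T
    offset = centroid - inv @ centroid
    rotated = ndimage.affine_transform(
        mask.values.astype(np.float32), inv, offset=offset, order=1, mode="constant"
    )
    return mask.with_values(rotated > 0.5)


def _shift_mask(values: np.ndarray, shift) -> np.ndarray:
    out = np.zeros_like(values)
    src = []
    dst = []
    for ax, s in enumerate(shift):
        n = values.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = values[tuple(src)]
    return out


def _best_lag(corr: np.ndarray, center) -> tuple:
    """Arg-max with ties broken toward the smallest shift magnitude."""
    best = corr.max()
    cands = np.argwhere(corr >= best - 1e-9) - np.asarray(center)
    mags = (cands**2).sum(axis=1)
    return tuple(int(v) for v in cands[np.argmin(mags)])


def align_translation_xcorr(mask: BinaryMask, reference: BinaryMask) -> RegistrationParams:
    """Integer shift aligning ``mask`` to ``reference`` on a shared grid.

    In-plane: 2-D cross-correlation of the axial mid-slices. Through-plane:
    1-D correlation of per-slice voxel counts, applied first so the
    mid-slices actually correspond. Ties go to the smallest shift.
    """
    if mask.shape != reference.shape:
        raise ValueError("masks must share a grid")
    if not mask.values.any() or not reference.values.any():
        raise ValueError("cannot align an empty mask")
    m = mask.values.astype(np.float32)
    r = reference.values.astype(np.float32)

    counts_m = m.sum(axis=(0, 1))
    counts_r = r.sum(axis=(0, 1))
    corr_z = signal.correlate(counts_r, counts_m, mode="full")
    (dz,) = _best_lag(corr_z, (len(counts_m) - 1,))

    mid = reference.shape[2] // 2
    m_shifted = _shift_mask(mask.values, (0, 0, dz)).astype(np.float32)
    slice_m = m_shifted[:, :, mid]
    slice_r = r[:, :, mid]
    if not slice_m.any() or not slice_r.any():
        # degenerate mid-slice; use the reference's fullest slice instead
        mid = int(np.argmax(counts_r))
        slice_m = m_shifted[:, :, mid]
        slice_r = r[:, :, mid]
    corr = signal.correlate(slice_r, slice_m, mode="full", method="fft")
    dx, dy = _best_lag(corr, (slice_m.shape[0] - 1, slice_m.shape[1] - 1))
    return RegistrationParams(shift_vox=(dx, dy, dz))


def _onto_grid(mask: BinaryMask, reference: BinaryMask) -> BinaryMask:
    """Place ``mask`` on the reference grid using physical coordinates."""
    if mask.shape == reference.shape and np.allclose(mask.origin, reference.origin):
        return mask
    offset = [
        int(round((mask.origin[ax] - reference.origin[ax]) / reference.spacing[ax]))
        for ax in range(3)
    ]
    out = np.zeros(reference.shape, dtype=bool)
    src, dst = [], []
    for ax in range(3):
        lo = offset[ax]
        hi = offset[ax] + mask.shape[ax]
        s0 = max(-lo, 0)
        d0 = max(lo, 0)
        d1 = min(hi, reference.shape[ax])
        if d1 <= d0:
            return BinaryMask(out, reference.spacing, reference.origin)
        src.append(slice(s0, s0 + (d1 - d0)))
        dst.append(slice(d0, d1))
    out[tuple(dst)] = mask.values[tuple(src)]
    return BinaryMask(out, reference.spacing, reference.origin)


def _apply_shift(mask: BinaryMask, params: RegistrationParams) -> BinaryMask:
    return mask.with_values(_shift_mask(mask.values, params.shift_vox))


def register_to_reference(
    mask: BinaryMask,
    reference: BinaryMask,
    angles_deg=(0.0, 0.0, 0.0),
    search: bool = False,
    search_range_deg: float = 10.0,
    search_step_deg: float = 2.0,
    target_mm: float = DEFAULT_ISO_MM,
) -> BinaryMask:
    """Upsample, rotate and shift ``mask`` onto the reference grid.

    With ``search=True`` the rotation is found by per-axis coordinate descent
    (two sweeps) over the +/- ``search_range_deg`` grid in
    ``search_step_deg`` steps, maximising post-shift Dice; the identity is
    always among the candidates. The returned mask lives on the (upsampled)
    reference grid and never has lower Dice than the unrotated, unshifted
    placement.
    """
    ref_iso = (
        reference
        if _is_isotropic(reference) and abs(reference.spacing[0] - target_mm) < 1e-9
        else upsample_isotropic(reference, target_mm)
    )
    moving = upsample_isotropic(mask, target_mm)
    moving = _onto_grid(moving, ref_iso)

    def score(m: BinaryMask) -> tuple[float, BinaryMask]:
        if not m.values.any():
            return 0.0, m
        params = align_translation_xcorr(m, ref_iso)
        shifted = _apply_shift(m, params)
        return dice_coefficient(shifted, ref_iso).value, shifted

    baseline = dice_coefficient(moving, ref_iso).value
    if search:
        grid = np.arange(-search_range_deg, search_range_deg + 1e-9, search_step_deg)
        best_angles = np.zeros(3)
        best_score, best_mask = score(moving)
        for _ in range(2):  # two coordinate-descent sweeps
            for ax in range(3):
                for a in grid:
                    cand = best_angles.copy()
                    cand[ax] = a
                    sc, sm = score(rotate_mask(moving, cand))
                    if sc > best_score:
                        best_score, best_mask, best_angles = sc, sm, cand
        result, result_score = best_mask, best_score
    else:
        rotated = rotate_mask(moving, angles_deg)
        result_score, result = score(rotated)

    if result_score < baseline:
        log.info("registration would lower Dice (%.3f < %.3f); keeping input", result_score, baseline)
        return moving
    return result
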