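"""Nodule segmentation: spherical VOI, two-cluster thresholding, connectivity.

The procedure mirrors semi-automatic nodule segmentation on CT: a spherical
volume of interest (VOI) of diameter d + 1.5 mm (spheres) or d + 6.5 mm
(spiked spheres) is extracted around the nodule centre; the in-VOI
intensities are split into two clusters by one-dimensional k-means (Lloyd
iteration, deterministic min/max initialisation); the brighter cluster is
the nodule; any component not 26-connected to the centre is discarded. The
segmentation is repeated three times with a small seeded perturbation of the
centre, standing in for observer variability in centre selection; reported
volumes and Dice values downstream average the three repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask, ImageVolume
from .phantom import NoduleSpec

__all__ = [
    "SegmentationResult",
    "extract_voi",
    "two_cluster_threshold",
    "keep_connected_to_center",
    "segment_nodule",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """One repeat of the triplicate segmentation."""

    mask: BinaryMask
    center_used_mm: tuple[float, float, float]
    voi_diameter_mm: float
    threshold_hu: float
    repeat_index: int  # 1..3


def extract_voi(volume: ImageVolume, center_mm, nodule: NoduleSpec):
    """Crop the bounding box of the spherical VOI around ``center_mm``.

    Returns ``(cropped_volume, voi_mask)`` where ``voi_mask`` marks voxels
    whose centres lie inside the VOI sphere; voxels outside the sphere are
    excluded from clustering. A VOI partially outside the volume is clipped
    with a warning; one entirely outside raises.
    """
    diameter = nodule.voi_diameter_mm
    r = diameter / 2
    c = np.asarray(center_mm, dtype=float)

    slices = []
    clipped = False
    for ax in range(3):
        lo = (c[ax] - r - volume.origin[ax]) / volume.spacing[ax]
        hi = (c[ax] + r - volume.origin[ax]) / volume.spacing[ax]
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi)) + 1
        if i0 < 0 or i1 > volume.shape[ax]:
            clipped = True
        i0, i1 = max(i0, 0), min(i1, volume.shape[ax])
        if i0 >= i1:
            raise ValueError("VOI lies entirely outside the volume")
        slices.append(slice(i0, i1))
    if clipped:
        log.warning("VOI partially outside the volume; clipped to bounds")

    sub_origin = tuple(
        volume.origin[ax] + slices[ax].start * volume.spacing[ax] for ax in range(3)
    )
    sub = ImageVolume(volume.values[tuple(slices)], volume.spacing, sub_origin)
    coords = [sub.voxel_centers(ax) - c[ax] for ax in range(3)]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    if not (d2 <= r * r).any():
        raise ValueError("VOI sphere contains no voxel centres")
    voi = BinaryMask(d2 <= r * r, sub.spacing, sub.origin)
    return sub, voi


def two_cluster_threshold(values) -> tuple[float, np.ndarray]:
    """1-D two-cluster k-means (Lloyd), deterministic min/max initialisation.

    Returns ``(threshold_hu, foreground)`` where the threshold is the
    midpoint of the final cluster means and ``foreground`` flags membership
    of the higher-mean cluster. Assignment uses the nearest centre, which in
    one dimension is equivalent to splitting at the midpoint; iteration stops
    when assignments are stable. Shift-equivariant: thresholding x + c gives
    threshold(x) + c.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("need at least two distinct intensity values")
    lo, hi = float(x.min()), float(x.max())
    split = (lo + hi) / 2
    for _ in range(200):
        fg = x > split
        if not fg.any() or fg.all():  # empty cluster: keep extremes apart
            fg = x >= split
        m_lo = x[~fg].mean()
        m_hi = x[fg].mean()
        new_split = (m_lo + m_hi) / 2
        if new_split == split:
            break
        split = new_split
    return float(split), x > split


def keep_connected_to_center(mask: BinaryMask, center_mm) -> BinaryMask:
    """Retain only the 26-connected component containing the centre voxel.

    If the voxel nearest ``center_mm`` is background, the component of the
    nearest foreground voxel within a one-voxel radius is used; failing
    that, an empty mask is returned with a warning.
    """
    values = mask.values
    if not values.any():
        return mask.with_values(np.zeros_like(values))
    idx = mask.index_of(center_mm)
    if not values[idx]:
        neighbourhood = tuple(
            slice(max(i - 1, 0), min(i + 2, n)) for i, n in zip(idx, mask.shape)
        )
        local = np.argwhere(values[neighbourhood])
        if local.size == 0:
            log.warning("no foreground voxel at or adjacent to the centre; empty mask")
            return mask.with_values(np.zeros_like(values))
        offsets = local + [s.start for s in neighbourhood] - idx
        nearest = local[np.argmin((offsets**2).sum(axis=1))]
        idx = tuple(nearest + [s.start for s in neighbourhood])
    labels, _ = ndimage.label(values, structure=_CONN26)
    return mask.with_values(labels == labels[idx])


def segment_nodule(
    volume: ImageVolume,
    center_mm,
    nodule: NoduleSpec,
    repeats: int = 3,
    perturb_mm: float | None = None,
    seed: int = 0,
) -> list[SegmentationResult]:
    """Triplicate segmentation with seeded centre perturbation.

    Repeat 1 uses the given centre; later repeats perturb it by a uniform
    offset within +/- ``perturb_mm`` per axis (default: one voxel, the
    largest spacing component). Each repeat runs VOI extraction, two-cluster
    thresholding inside the VOI and the connectivity filter.
    """
    if perturb_mm is None:
        perturb_mm = max(volume.spacing)
    rng = np.random.default_rng(seed)
    center = np.asarray(center_mm, dtype=float)
    results = []
    for k in range(1, repeats + 1):
        offset = np.zeros(3) if k == 1 else rng.uniform(-perturb_mm, perturb_mm, 3)
        c = tuple(center + offset)
        sub, voi = extract_voi(volume, c, nodule)
        threshold, fg = two_cluster_threshold(sub.values[voi.values])
        seg = np.zeros(sub.shape, dtype=bool)
        seg[voi.values] = fg
        mask = keep_connected_to_center(
            BinaryMask(seg, sub.spacing, sub.origin), c
        )
        results.append(
            SegmentationResult(
                mask=mask,
                center_used_mm=c,
                voi_diameter_mm=nodule.voi_diameter_mm,
                threshold_hu=threshold,
                repeat_index=k,
            )
        )
    return results
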