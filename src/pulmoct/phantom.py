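"""Digital lung phantom construction.

Builds the ground-truth objects the analysis pipeline consumes: a lung-like
background volume with tubular vessel clutter, parametric nodules (spheres for
benign-style lesions, spheres with conical spikes for malignant-style lesions),
and wire-phantom images for spatial-resolution measurement.

The lung interior defaults to the elevated "powder-filled" level of about
-580 HU; vessels, walls and nodules share a soft-tissue-like level in
[-130, -90] HU. An air-like background of about -875 HU is available through
configuration. All structures are rasterised deterministically: the same scene
(including seeds) yields a bit-identical phantom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask, ImageVolume

__all__ = [
    "GridSpec",
    "NoduleSpec",
    "VesselParams",
    "PhantomScene",
    "WirePhantomSpec",
    "make_grid",
    "generate_sphere_mask",
    "generate_spiked_sphere_mask",
    "generate_vessel_tree",
    "assemble_phantom",
    "generate_wire_image",
    "voi_diameter_mm",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Margin (mm) added to the nodule diameter to form the spherical VOI used for
#: segmentation: d + 1.5 for plain spheres, d + 6.5 for spiked spheres.
VOI_MARGIN_MM = {"sphere": 1.5, "spiked_sphere": 6.5}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a sampling grid: shape, voxel spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class NoduleSpec:
    """Parametric nodule definition.

    ``kind`` is ``"sphere"`` (benign-style) or ``"spiked_sphere"``
    (malignant-style, a sphere with conical spikes). Spikes are cones whose
    base (radius ``spike_length_mm * tan(spike_base_deg)``) sits on the sphere
    surface and whose apex lies ``spike_length_mm`` further out radially. The
    first six spikes are axis-aligned; any further spikes point in seeded
    random directions.
    """

    kind: str
    diameter_mm: float
    center_mm: tuple[float, float, float]
    n_spikes: int = 12
    spike_length_mm: float = 2.5
    spike_base_deg: float = 20.0
    spike_seed: int = 0

    def __post_init__(self):
        if self.kind not in ("sphere", "spiked_sphere"):
            raise ValueError(f"unknown nodule kind {self.kind!r}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.kind == "spiked_sphere":
            if self.n_spikes < 1:
                raise ValueError(
                    "spiked_sphere requires n_spikes >= 1 (use kind='sphere')"
                )
            if self.spike_length_mm <= 0:
                raise ValueError("spike_length_mm must be positive")
            # Sphere plus spikes must fit inside the segmentation VOI of
            # diameter d + 6.5 mm: r + L <= (d + 6.5) / 2.
            if self.spike_length_mm > VOI_MARGIN_MM["spiked_sphere"] / 2:
                raise ValueError(
                    "spike_length_mm must not exceed "
                    f"{VOI_MARGIN_MM['spiked_sphere'] / 2:.2f} mm so the spiked "
                    "nodule fits inside its VOI"
                )

    @property
    def voi_diameter_mm(self) -> float:
        return self.diameter_mm + VOI_MARGIN_MM[self.kind]


def voi_diameter_mm(nodule: NoduleSpec) -> float:
    """Diameter (mm) of the spherical segmentation VOI for a nodule."""
    return nodule.voi_diameter_mm


@dataclass(frozen=True)
class VesselParams:
    """Branching-tube parameters for the procedural vessel tree."""

    depth: int = 4
    root_radius_mm: float = 1.0
    root_length_mm: float = 12.0
    radius_decay: float = 0.7
    length_decay: float = 0.8
    branch_angle_deg: tuple[float, float] = (20.0, 40.0)
    n_children: int = 2

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 < self.radius_decay < 1:
            raise ValueError("radius_decay must lie in (0, 1)")
        if self.root_radius_mm <= 0 or self.root_length_mm <= 0:
            raise ValueError("root radius and length must be positive")


@dataclass
class PhantomScene:
    """Full description of a digital lung phantom."""

    grid: GridSpec
    nodules: list[NoduleSpec] = field(default_factory=list)
    lung_background_hu: float = -580.0
    structure_hu: float = -110.0
    vessel_seed: int = 7
    vessel_params: VesselParams = field(default_factory=VesselParams)
    vessel_root_mm: tuple[float, float, float] | None = None
    vessel_direction: tuple[float, float, float] = (1.0, 0.3, 0.1)

    def __post_init__(self):
        if not -130 <= self.structure_hu <= -90:
            raise ValueError("structure_hu must lie in [-130, -90] HU")


@dataclass(frozen=True)
class WirePhantomSpec:
    """A thin wire parallel to z, for point-spread / MTF measurement."""

    wire_diameter_mm: float
    grid: GridSpec
    wire_hu: float = 3000.0
    background_hu: float = 0.0
    center_xy_mm: tuple[float, float] | None = None  # default: grid centre

    def __post_init__(self):
        if self.wire_diameter_mm <= 0:
            raise ValueError("wire_diameter_mm must be positive")


# ---------------------------------------------------------------------------
# grids and simple shapes
# ---------------------------------------------------------------------------


def make_grid(shape, spacing_mm, fill_hu: float = 0.0, origin_mm=(0.0, 0.0, 0.0)) -> ImageVolume:
    """Uniformly filled volume of the given geometry."""
    shape = tuple(int(n) for n in shape)
    if any(n < 1 for n in shape):
        raise ValueError(f"shape components must be >= 1, got {shape}")
    values = np.full(shape, float(fill_hu), dtype=np.float32)
    return ImageVolume(values, spacing_mm, origin_mm)


def _axes(grid: GridSpec):
    return [
        grid.origin_mm[ax] + np.arange(grid.shape[ax]) * grid.spacing_mm[ax]
        for ax in range(3)
    ]


def _bbox_slices(grid: GridSpec, lo_mm, hi_mm):
    """Index slices covering the physical box [lo, hi] (clipped to the grid)."""
    sl = []
    for ax in range(3):
        i0 = int(np.floor((lo_mm[ax] - grid.origin_mm[ax]) / grid.spacing_mm[ax]))
        i1 = int(np.ceil((hi_mm[ax] - grid.origin_mm[ax]) / grid.spacing_mm[ax])) + 1
        sl.append(slice(max(i0, 0), min(i1, grid.shape[ax])))
    return tuple(sl)


def _require_inside(grid: GridSpec, lo_mm, hi_mm, what: str):
    for ax in range(3):
        gmin = grid.origin_mm[ax] - grid.spacing_mm[ax] / 2
        gmax = gmin + grid.shape[ax] * grid.spacing_mm[ax]
        if lo_mm[ax] < gmin - 1e-9 or hi_mm[ax] > gmax + 1e-9:
            raise ValueError(f"{what} exceeds grid bounds along axis {ax}")


def generate_sphere_mask(spec: NoduleSpec, grid: GridSpec) -> BinaryMask:
    """Voxelise a sphere: a voxel is set iff its centre lies within radius."""
    if spec.kind != "sphere":
        raise ValueError("generate_sphere_mask requires kind='sphere'")
    r = spec.diameter_mm / 2
    c = np.asarray(spec.center_mm, dtype=float)
    _require_inside(grid, c - r, c + r, "sphere")
    values = np.zeros(grid.shape, dtype=bool)
    sl = _bbox_slices(grid, c - r, c + r)
    ax = _axes(grid)
    dx = ax[0][sl[0]] - c[0]
    dy = ax[1][sl[1]] - c[1]
    dz = ax[2][sl[2]] - c[2]
    d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    values[sl] = d2 <= r * r
    return BinaryMask(values, grid.spacing_mm, grid.origin_mm)


def _spike_directions(spec: NoduleSpec) -> np.ndarray:
    axis_dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    n_axis = min(spec.n_spikes, 6)
    dirs = [axis_dirs[:n_axis]]
    n_rand = spec.n_spikes - n_axis
    if n_rand > 0:
        rng = np.random.default_rng(spec.spike_seed)
        v = rng.standard_normal((n_rand, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        dirs.append(v)
    return np.concatenate(dirs, axis=0)


def generate_spiked_sphere_mask(spec: NoduleSpec, grid: GridSpec) -> BinaryMask:
    """Voxelise a sphere with conical spikes (union of sphere and cones)."""
    if spec.kind != "spiked_sphere":
        raise ValueError("generate_spiked_sphere_mask requires kind='spiked_sphere'")
    r = spec.diameter_mm / 2
    L = spec.spike_length_mm
    c = np.asarray(spec.center_mm, dtype=float)
    reach = r + L
    _require_inside(grid, c - reach, c + reach, "spiked sphere")

    sphere = NoduleSpec(kind="sphere", diameter_mm=spec.diameter_mm, center_mm=spec.center_mm)
    mask = generate_sphere_mask(sphere, grid)
    values = mask.values

    base_radius = L * np.tan(np.deg2rad(spec.spike_base_deg))
    ax = _axes(grid)
    for u in _spike_directions(spec):
        # Cone from base centre (on the sphere surface) to apex at r + L.
        lo = c - reach
        hi = c + reach
        sl = _bbox_slices(grid, lo, hi)
        dx = ax[0][sl[0]] - c[0]
        dy = ax[1][sl[1]] - c[1]
        dz = ax[2][sl[2]] - c[2]
        px = dx[:, None, None]
        py = dy[None, :, None]
        pz = dz[None, None, :]
        t = px * u[0] + py * u[1] + pz * u[2]  # distance along spike axis
        perp2 = (px - t * u[0]) ** 2 + (py - t * u[1]) ** 2 + (pz - t * u[2]) ** 2
        s = t - r  # 0 at the base, L at the apex
        with np.errstate(invalid="ignore"):
            allowed = base_radius * (1 - s / L)
        inside = (s >= 0) & (s <= L) & (perp2 <= allowed**2)
        values[sl] |= inside
    return mask.with_values(values)


def generate_nodule_mask(spec: NoduleSpec, grid: GridSpec) -> BinaryMask:
    if spec.kind == "sphere":
        return generate_sphere_mask(spec, grid)
    return generate_spiked_sphere_mask(spec, grid)


# ---------------------------------------------------------------------------
# vessel tree
# ---------------------------------------------------------------------------


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _perpendicular(u):
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, helper)
    return p / np.linalg.norm(p)


def _tree_segments(params: VesselParams, rng: np.random.Generator, start, direction):
    """List of (p0, p1, radius) capsules for the branching tree."""
    segments = []

    def grow(p0, u, radius, length, level):
        p1 = p0 + u * length
        segments.append((p0.copy(), p1.copy(), radius))
        if level >= params.depth:
            return
        for _ in range(params.n_children):
            ang = np.deg2rad(rng.uniform(*params.branch_angle_deg))
            azi = rng.uniform(0, 2 * np.pi)
            e1 = _perpendicular(u)
            e2 = np.cross(u, e1)
            child = (
                np.cos(ang) * u
                + np.sin(ang) * (np.cos(azi) * e1 + np.sin(azi) * e2)
            )
            grow(
                p1,
                child / np.linalg.norm(child),
                radius * params.radius_decay,
                length * params.length_decay,
                level + 1,
            )

    grow(np.asarray(start, dtype=float), _unit(direction), params.root_radius_mm,
         params.root_length_mm, 1)
    return segments


def _rasterise_capsule(values: np.ndarray, grid: GridSpec, p0, p1, radius):
    lo = np.minimum(p0, p1) - radius
    hi = np.maximum(p0, p1) + radius
    sl = _bbox_slices(grid, lo, hi)
    if any(s.start >= s.stop for s in sl):
        return
    ax = _axes(grid)
    X = ax[0][sl[0]][:, None, None]
    Y = ax[1][sl[1]][None, :, None]
    Z = ax[2][sl[2]][None, None, :]
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        t = np.zeros_like(X)
    else:
        t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
        t = np.clip(t, 0.0, 1.0)
    cx = p0[0] + t * d[0]
    cy = p0[1] + t * d[1]
    cz = p0[2] + t * d[2]
    dist2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    values[sl] |= dist2 <= radius * radius


def generate_vessel_tree(
    seed: int,
    params: VesselParams,
    grid: GridSpec,
    start_mm=None,
    direction=(1.0, 0.3, 0.1),
) -> BinaryMask:
    """Seeded procedural branching-tube structure (vessel-like clutter).

    The tree grows from ``start_mm`` (default: near the -x face, mid y/z) and
    is clipped to the grid. Same seed and parameters give identical masks.
    """
    rng = np.random.default_rng(seed)
    if start_mm is None:
        start_mm = (
            grid.origin_mm[0],
            grid.origin_mm[1] + (grid.shape[1] - 1) * grid.spacing_mm[1] / 2,
            grid.origin_mm[2] + (grid.shape[2] - 1) * grid.spacing_mm[2] / 2,
        )
    values = np.zeros(grid.shape, dtype=bool)
    for p0, p1, radius in _tree_segments(params, rng, start_mm, direction):
        _rasterise_capsule(values, grid, p0, p1, radius)
    return BinaryMask(values, grid.spacing_mm, grid.origin_mm)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------


def _voi_sphere_indices(grid: GridSpec, center_mm, diameter_mm):
    """Bounding slices plus boolean ball for a spherical VOI."""
    r = diameter_mm / 2
    c = np.asarray(center_mm, dtype=float)
    sl = _bbox_slices(grid, c - r, c + r)
    ax = _axes(grid)
    dx = ax[0][sl[0]] - c[0]
    dy = ax[1][sl[1]] - c[1]
    dz = ax[2][sl[2]] - c[2]
    ball = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        <= r * r
    )
    return sl, ball


def _reference_mask(nodule_values, vessel_values, grid, nodule: NoduleSpec) -> BinaryMask:
    """Digital nodule plus vessel voxels 26-connected to it inside its VOI."""
    sl, ball = _voi_sphere_indices(grid, nodule.center_mm, nodule.voi_diameter_mm)
    local = (nodule_values[sl] | vessel_values[sl]) & ball
    labels, n = ndimage.label(local, structure=_CONN26)
    ref = np.zeros(grid.shape, dtype=bool)
    if n:
        nodule_labels = np.unique(labels[nodule_values[sl]])
        nodule_labels = nodule_labels[nodule_labels > 0]
        ref[sl] = np.isin(labels, nodule_labels)
    # the nodule itself is always part of the reference, even outside the VOI
    ref |= nodule_values
    return BinaryMask(ref, grid.spacing_mm, grid.origin_mm)


def assemble_phantom(scene: PhantomScene):
    """Render a scene into an HU volume and per-nodule reference masks.

    Returns ``(volume, references)`` where ``references[i]`` is the exact
    digital shape of ``scene.nodules[i]`` together with any vessel voxels
    connected to it inside that nodule's VOI (these attached parts belong to
    the standard of reference, mirroring how segmentation will see them).
    Overlapping nodules are merged with a logged warning.
    """
    grid = scene.grid
    vessels = generate_vessel_tree(
        scene.vessel_seed,
        scene.vessel_params,
        grid,
        start_mm=scene.vessel_root_mm,
        direction=scene.vessel_direction,
    )
    nodule_masks = [generate_nodule_mask(n, grid) for n in scene.nodules]

    occupancy = np.zeros(grid.shape, dtype=np.uint8)
    for m in nodule_masks:
        occupancy += m.values
    if (occupancy > 1).any():
        log.warning("nodules overlap; union taken")

    structure = vessels.values.copy()
    for m in nodule_masks:
        structure |= m.values
    values = np.full(grid.shape, scene.lung_background_hu, dtype=np.float32)
    values[structure] = scene.structure_hu
    volume = ImageVolume(values, grid.spacing_mm, grid.origin_mm)

    references = [
        _reference_mask(m.values, vessels.values, grid, n)
        for m, n in zip(nodule_masks, scene.nodules)
    ]
    return volume, references


# ---------------------------------------------------------------------------
# wire phantom
# ---------------------------------------------------------------------------


def _disk_pixel_area(x0, x1, y0, y1, r):
    """Exact area of the intersection of the disk x²+y²<=r² with a rectangle.

    Computed as the x-integral of the clipped chord length, split at every
    point where the integrand changes analytic branch, with Gauss-Legendre
    quadrature on each smooth piece.
    """
    a = max(x0, -r)
    b = min(x1, r)
    if a >= b:
        return 0.0
    breaks = {a, b}
    for y in (y0, y1):
        if abs(y) < r:
            x = np.sqrt(r * r - y * y)
            for cand in (-x, x):
                if a < cand < b:
                    breaks.add(cand)
    nodes, weights = np.polynomial.legendre.leggauss(32)
    total = 0.0
    pts = sorted(breaks)
    for lo, hi in zip(pts[:-1], pts[1:]):
        x = (hi - lo) / 2 * nodes + (hi + lo) / 2
        h = np.sqrt(np.maximum(r * r - x * x, 0.0))
        length = np.minimum(y1, h) - np.maximum(y0, -h)
        total += (hi - lo) / 2 * float(np.sum(weights * np.maximum(length, 0.0)))
    return total


def generate_wire_image(spec: WirePhantomSpec) -> ImageVolume:
    """Render a wire parallel to z by exact pixel-disk area overlap.

    Each in-plane pixel value is ``background + (wire - background) * a`` where
    ``a`` is the fraction of the pixel area covered by the wire cross-section;
    identical across z. Area sampling (rather than point sampling) avoids the
    severe aliasing a 100 µm wire would suffer on a 130 µm grid.
    """
    grid = spec.grid
    sx, sy, _ = grid.spacing_mm
    nx, ny, nz = grid.shape
    if spec.wire_diameter_mm >= min(nx * sx, ny * sy):
        raise ValueError("wire diameter must be smaller than the grid extent")
    if spec.center_xy_mm is None:
        cx = grid.origin_mm[0] + (nx - 1) * sx / 2
        cy = grid.origin_mm[1] + (ny - 1) * sy / 2
    else:
        cx, cy = spec.center_xy_mm
    r = spec.wire_diameter_mm / 2

    xs = grid.origin_mm[0] + np.arange(nx) * sx
    ys = grid.origin_mm[1] + np.arange(ny) * sy
    plane = np.zeros((nx, ny), dtype=np.float64)
    # only pixels whose rectangle can intersect the disk need the quadrature
    half_diag = np.hypot(sx, sy) / 2
    ii = np.nonzero(np.abs(xs - cx) <= r + sx)[0]
    jj = np.nonzero(np.abs(ys - cy) <= r + sy)[0]
    pixel_area = sx * sy
    for i in ii:
        x0, x1 = xs[i] - sx / 2 - cx, xs[i] + sx / 2 - cx
        for j in jj:
            y0, y1 = ys[j] - sy / 2 - cy, ys[j] + sy / 2 - cy
            if np.hypot(max(abs(x0), abs(x1)), max(abs(y0), abs(y1))) <= r:
                plane[i, j] = 1.0  # pixel fully inside the wire
            else:
                plane[i, j] = _disk_pixel_area(x0, x1, y0, y1, r) / pixel_area
    hu = spec.background_hu + (spec.wire_hu - spec.background_hu) * plane
    values = np.repeat(hu[:, :, None], nz, axis=2).astype(np.float64)
    return ImageVolume(values, grid.spacing_mm, grid.origin_mm)
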