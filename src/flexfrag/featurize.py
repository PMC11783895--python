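"""Fragment featurization: point clouds, Gaussian voxels, Hilbert images,
surface meshes.

The four representations deliberately carry *no* atom-type information: the
voxel kernel uses a uniform weight of 1 per atom so that models must learn
shape, not a hidden element encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage import measure

from .fragments import Fragment
from .hilbert import hilbert_cells

__all__ = [
    "PointCloud",
    "VoxelGrid",
    "HilbertImage",
    "SurfaceMesh",
    "prepare_pointcloud",
    "voxelize",
    "flatten_voxels",
    "downsample_curve",
    "make_hilbert_image",
    "compute_surface",
    "surface_pointcloud",
]

log = logging.getLogger(__name__)

#: default voxel-grid parameters: 32^3 voxels over a 16 A cube (0.5 A),
#: Gaussian smoothness 1 A, hard cutoff 12 A, uniform atom weight 1
GRID_SIZE = 32
BOX_EDGE = 16.0
SIGMA = 1.0
CUTOFF = 12.0

#: surface lattice spacing (A) and smoothing steps
SURFACE_SPACING = 0.35
SURFACE_SMOOTHING_STEPS = 1
PROBE_RADIUS = 1.4
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}

#: per-task point-cloud target sizes: single / dipeptide coordinates and
#: surface vertices
TARGET_POINTS_SINGLE = 24
TARGET_POINTS_DUAL = 42
TARGET_POINTS_SURFACE = 1500


@dataclass
class PointCloud:
    """Fixed-size point set, min-shifted, padded/subsampled and shuffled."""

    points: np.ndarray  # (K, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)


@dataclass
class VoxelGrid:
    """Gaussian atom-density values on a cubic lattice.

    ``values[i, j, k]`` is the density at the voxel center
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    values: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    box_edge: float = BOX_EDGE
    sigma: float = SIGMA
    cutoff: float = CUTOFF

    @property
    def spacing(self) -> float:
        return self.box_edge / self.values.shape[0]

    def voxel_centers(self) -> np.ndarray:
        n = self.values.shape[0]
        h = self.spacing
        gx, gy, gz = np.meshgrid(
            self.origin[0] + (np.arange(n) + 0.5) * h,
            self.origin[1] + (np.arange(n) + 0.5) * h,
            self.origin[2] + (np.arange(n) + 0.5) * h,
            indexing="ij",
        )
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


@dataclass
class HilbertImage:
    """128 x 128 image obtained by curve-ordered flattening of a voxel grid."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, float)


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) vertex indices
    spacing: float = SURFACE_SPACING
    smoothing_steps: int = SURFACE_SMOOTHING_STEPS

    def area(self) -> float:
        v = self.vertices
        t = v[self.faces]
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def prepare_pointcloud(points, target_count: int, seed: int = 0) -> PointCloud:
    """Shift to the positive octant, pad or subsample to a fixed count, shuffle.

    Points are first shifted by subtracting the per-axis minimum; too-small
    sets are padded with copies of the origin, too-large sets are uniformly
    subsampled without replacement; the result is randomly permuted so that
    downstream models cannot associate features with point order.
    Deterministic for a given ``seed``.
    """
    if isinstance(points, Fragment):
        points = points.coords
    pts = np.asarray(points, float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("cannot prepare an empty point set")
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    rng = np.random.default_rng(seed)
    shifted = pts - pts.min(axis=0)
    n = shifted.shape[0]
    if n > target_count:
        keep = rng.choice(n, size=target_count, replace=False)
        out = shifted[keep]
    elif n < target_count:
        pad = np.zeros((target_count - n, 3))
        out = np.concatenate([shifted, pad], axis=0)
    else:
        out = shifted.copy()
    out = out[rng.permutation(target_count)]
    return PointCloud(out)


# ---------------------------------------------------------------------------
# voxels
# ---------------------------------------------------------------------------

def voxelize(fragment, grid_size: int = GRID_SIZE, box_edge: float = BOX_EDGE,
             sigma: float = SIGMA, cutoff: float = CUTOFF,
             center: bool = True) -> VoxelGrid:
    """Gaussian-density voxelization with uniform atom weight.

    The fragment is translated so its geometric center (mean over all atoms)
    coincides with the box center; the value at a voxel center ``v`` is
    ``sum_atoms exp(-d(v, atom)^2 / (2 sigma^2))`` for ``d <= cutoff``.
    Atoms outside the box still contribute to in-box voxels within the
    cutoff (a warning is logged).
    """
    coords = fragment.coords if isinstance(fragment, Fragment) else \
        np.asarray(fragment, float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValueError("cannot voxelize an empty fragment")
    grid = VoxelGrid(np.zeros((grid_size,) * 3), np.zeros(3), box_edge,
                     sigma, cutoff)
    if center:
        shift = box_edge / 2.0 - coords.mean(axis=0)
        coords = coords + shift
    if (coords.min() < 0) or (coords.max() > box_edge):
        log.warning("atoms outside the %g A box; they still contribute "
                    "within the cutoff", box_edge)
    centers = grid.voxel_centers()
    d2 = cdist(centers, coords, metric="sqeuclidean")
    kernel = np.exp(-d2 / (2.0 * sigma * sigma))
    kernel[d2 > cutoff * cutoff] = 0.0
    grid.values = kernel.sum(axis=1).reshape((grid_size,) * 3)
    return grid


# ---------------------------------------------------------------------------
# Hilbert images
# ---------------------------------------------------------------------------

def flatten_voxels(grid) -> np.ndarray:
    """Flatten a 32^3 grid to a vector along the order-5 3D Hilbert curve."""
    values = grid.values if isinstance(grid, VoxelGrid) else np.asarray(grid)
    if values.shape != (32, 32, 32):
        raise ValueError(f"expected a 32^3 grid, got {values.shape}")
    cells = hilbert_cells(5, 3)
    return values[cells[:, 0], cells[:, 1], cells[:, 2]]


def downsample_curve(vec: np.ndarray, factor: int = 2) -> np.ndarray:
    """Aggregate adjacent non-overlapping pairs along the curve (mean)."""
    vec = np.asarray(vec, float)
    if vec.ndim != 1 or vec.size % factor:
        raise ValueError(f"vector length {vec.size} not divisible by {factor}")
    return vec.reshape(-1, factor).mean(axis=1)


def make_hilbert_image(grid) -> HilbertImage:
    """Fold a 32^3 voxel grid into a 128 x 128 image.

    The grid is flattened along the order-5 3D Hilbert curve (2^15 cells),
    downsampled 2x by pair means (2^14), and laid out along the order-7 2D
    Hilbert curve (128 x 128 pixels).  The whole map is linear in the grid.
    """
    vec = downsample_curve(flatten_voxels(grid), 2)
    cells = hilbert_cells(7, 2)
    pixels = np.zeros((128, 128))
    pixels[cells[:, 0], cells[:, 1]] = vec
    return HilbertImage(pixels)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def compute_surface(fragment, spacing: float = SURFACE_SPACING,
                    smoothing_steps: int = SURFACE_SMOOTHING_STEPS,
                    probe_radius: float = PROBE_RADIUS) -> SurfaceMesh:
    """Triangulated molecular envelope from atom spheres.

    A signed field (positive inside any probe-inflated atom sphere) is
    sampled on a ``spacing`` lattice, the zero isosurface is extracted by
    marching cubes, and the mesh is relaxed by ``smoothing_steps`` passes of
    uniform Laplacian smoothing.
    """
    if isinstance(fragment, Fragment):
        coords = fragment.coords
        radii = np.array([VDW_RADII.get(e, 1.7) for e in fragment.elements])
    else:
        coords = np.asarray(fragment, float).reshape(-1, 3)
        radii = np.full(coords.shape[0], VDW_RADII["C"])
    if coords.shape[0] == 0:
        raise ValueError("cannot build a surface for an empty fragment")
    radii = radii + probe_radius
    pad = radii.max() + 2 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + np.arange(shape[k]) * spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    # signed "inside-ness": max over atoms of (r_i - d_i); > 0 inside
    d = cdist(points, coords)
    fieldv = (radii[None, :] - d).max(axis=1).reshape(shape)
    verts, faces, _, _ = measure.marching_cubes(fieldv, level=0.0,
                                                spacing=(spacing,) * 3)
    verts = verts + lo
    for _ in range(smoothing_steps):
        verts = _laplacian_smooth(verts, faces)
    return SurfaceMesh(verts, faces, spacing, smoothing_steps)


def _laplacian_smooth(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One pass of uniform Laplacian smoothing (vertex -> neighbor mean)."""
    n = vertices.shape[0]
    accum = np.zeros_like(vertices)
    counts = np.zeros(n)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        i, j = faces[:, a], faces[:, b]
        np.add.at(accum, i, vertices[j])
        np.add.at(accum, j, vertices[i])
        np.add.at(counts, i, 1)
        np.add.at(counts, j, 1)
    counts[counts == 0] = 1
    return accum / counts[:, None]


def surface_pointcloud(fragment, target_count: int = TARGET_POINTS_SURFACE,
                       seed: int = 0, **surface_kwargs) -> PointCloud:
    """Point cloud of surface-mesh vertices, prepared to a fixed count."""
    mesh = compute_surface(fragment, **surface_kwargs)
    return prepare_pointcloud(mesh.vertices, target_count, seed)
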