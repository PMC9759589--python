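"""Low-level 3D geometry on binary tumor masks.

A tumor model is a binary occupancy grid on a regular (possibly anisotropic)
voxel lattice with physical spacing in millimetres.  All geometry is done in
world coordinates: voxel index ``(i, j, k)`` maps to
``world = origin + index * spacing`` (0-based, node-centered voxel centers).

Surfaces are extracted as closed triangle meshes with a marching-cubes
iso-surface at level 0.5, which avoids the staircase bias a voxel-face surface
would introduce into surface/volume-derived shape metrics.  Volumes are
reported in cm^3 and areas in cm^2 (internal computations in mm).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

logger = logging.getLogger("tsiplan")

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0


class EmptyMaskError(ValueError):
    """Raised when a geometry operation receives a mask with no foreground."""


class DegenerateShapeError(ValueError):
    """Raised when the foreground is too small/degenerate for the operation."""


class NonClosedMeshError(ValueError):
    """Raised when a volume is requested for a surface that is not closed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelMask:
    """3D binary occupancy grid with physical voxel spacing (mm)."""

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be strictly positive")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_foreground(self) -> int:
        return int(self.occupancy.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_count_volume_cm3(self) -> float:
        """Volume as foreground-voxel count times voxel volume (cm^3)."""
        return self.n_foreground * self.voxel_volume_mm3 / MM3_PER_CM3

    def n_components(self) -> int:
        """Number of 6-connected foreground components."""
        _, n = ndimage.label(self.occupancy)
        return int(n)

    def foreground_coordinates(self) -> np.ndarray:
        """World coordinates (mm) of foreground voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.occupancy).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.occupancy.astype(np.uint8), affine)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "VoxelMask":
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(t) for t in img.affine[:3, 3])
        data = np.asarray(img.dataobj) > 0.5
        return cls(data, spacing, origin)


@dataclass
class TriMesh:
    """Closed, consistently oriented triangle surface in world mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    def triangle_areas_mm2(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def save_ply(self, path: str) -> None:
        """Write an ASCII PLY for external inspection."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


@dataclass
class PrincipalAxes:
    """Eigenvalues (mm^2) of the second central moment of voxel centers.

    ``semi_axes = 2 * sqrt(lambda)`` — the common radiomics convention; for a
    solid ball of radius r the moment eigenvalues are r^2/5 so each semi-axis
    is 2r/sqrt(5) ~= 0.894 r.
    """

    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        ev = np.clip(ev, 0.0, None)
        self.eigenvalues = np.sort(ev)[::-1]

    @property
    def lambda_major(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def lambda_minor(self) -> float:
        return float(self.eigenvalues[1])

    @property
    def lambda_least(self) -> float:
        return float(self.eigenvalues[2])

    @property
    def semi_axes_mm(self) -> np.ndarray:
        return 2.0 * np.sqrt(self.eigenvalues)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def extract_mesh(mask: VoxelMask, smooth_sigma_mm: float | None = None) -> TriMesh:
    """Marching-cubes iso-surface of the binary grid at the 0.5 transition.

    The binary field is pre-smoothed with a small spacing-aware Gaussian
    (default sigma: one voxel along the finest axis), the standard
    anti-aliasing step that removes the staircase bias of meshing a binary
    grid directly.  Because smoothing shifts the nominal 0.5 level inward on
    convex bodies (mean-curvature bias) and can drop thin structures below
    0.5 entirely, the iso-level is chosen volume-matched instead of fixed:
    the number of grid samples above the level equals the foreground voxel
    count, so mesh volume tracks voxel-count volume and thin structures keep
    a surface.
    Vertices are in world mm; faces are oriented so the signed volume is
    positive.  Multiple foreground components are meshed together with a
    logged warning.
    """
    if mask.n_foreground == 0:
        raise EmptyMaskError("empty-mask: no foreground voxels")
    if mask.n_components() > 1:
        msg = f"mask has {mask.n_components()} foreground components; meshing union"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if smooth_sigma_mm is None:
        smooth_sigma_mm = min(mask.spacing)
    # pad with background voxels so surfaces at the grid edge close
    pad = 2
    padded = np.pad(mask.occupancy, pad).astype(np.float32)
    if smooth_sigma_mm > 0:
        sigma_vox = smooth_sigma_mm / np.asarray(mask.spacing)
        field = ndimage.gaussian_filter(padded, sigma=sigma_vox)
        level = _volume_matched_level(field, mask.n_foreground)
    else:
        field = padded
        level = 0.5
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=mask.spacing)
    verts = verts - pad * np.asarray(mask.spacing) + np.asarray(mask.origin)
    # weld coincident vertices and drop collapsed (zero-area) faces; welding
    # keeps the surface watertight where marching cubes emitted slivers
    uverts, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    mesh = TriMesh(uverts, faces[distinct])
    if _signed_volume_mm3(mesh) < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _volume_matched_level(field: np.ndarray, n_foreground: int) -> float:
    """Iso-level whose superlevel set holds exactly ``n_foreground`` samples."""
    flat = field.ravel()
    part = np.partition(flat, flat.size - n_foreground)
    v_in = float(part[flat.size - n_foreground])  # smallest of the top n
    v_out = float(part[: flat.size - n_foreground].max()) if flat.size > n_foreground else 0.0
    level = 0.5 * (v_in + v_out)
    if level >= v_in:  # plateau tie: nudge just below the inside value
        level = v_in - 1e-6
    return level


def _signed_volume_mm3(mesh: TriMesh) -> float:
    v = mesh.vertices
    f = mesh.faces
    return float(
        np.einsum(
            "ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])
        ).sum()
        / 6.0
    )


def mesh_volume(mesh: TriMesh) -> float:
    """Divergence-theorem signed volume of a closed mesh, in cm^3."""
    if not mesh.is_closed():
        raise NonClosedMeshError("non-closed-mesh: cannot compute volume")
    return _signed_volume_mm3(mesh) / MM3_PER_CM3


def mesh_surface_area(mesh: TriMesh) -> float:
    """Total triangle area of the surface, in cm^2."""
    return float(mesh.triangle_areas_mm2().sum()) / MM2_PER_CM2


def principal_axes(mask: VoxelMask) -> PrincipalAxes:
    """Eigen-decomposition of the second central moment of foreground centers."""
    if mask.n_foreground == 0:
        raise EmptyMaskError("empty-mask: no foreground voxels")
    if mask.n_foreground < 4:
        raise DegenerateShapeError("degenerate-shape: fewer than 4 foreground voxels")
    coords = mask.foreground_coordinates()
    centered = coords - coords.mean(axis=0)
    moment = centered.T @ centered / len(centered)
    eigenvalues = np.linalg.eigvalsh(moment)
    return PrincipalAxes(eigenvalues)


def max_3d_diameter(mesh_or_points) -> float:
    """Maximum pairwise Euclidean distance over mesh vertices (mm).

    Reduces to convex-hull vertices first; falls back to all points for
    degenerate (flat/collinear) inputs.
    """
    pts = mesh_or_points.vertices if isinstance(mesh_or_points, TriMesh) else np.asarray(mesh_or_points, float)
    if len(pts) < 2:
        raise DegenerateShapeError("degenerate-shape: need >= 2 points for a diameter")
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


# -- minimum enclosing sphere ------------------------------------------------


def _circumsphere(pts: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Smallest sphere with all of ``pts`` (1..4 points) on its boundary."""
    p0 = pts[0]
    if len(pts) == 1:
        return p0.copy(), 0.0
    d = pts[1:] - p0
    gram = d @ d.T
    rhs = 0.5 * np.einsum("ij,ij->i", d, d)
    try:
        x = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError:
        return None
    center = p0 + x @ d
    radius = float(np.linalg.norm(center - p0))
    return center, radius


def _ball_of_support(pts: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact minimum enclosing sphere of a small point set (brute force).

    Enumerates boundary subsets of size 1..4 and keeps the smallest sphere
    that contains all points.  Returns (center, radius, support subset).
    """
    n = len(pts)
    best: tuple[np.ndarray, float, np.ndarray] | None = None
    for k in range(1, min(4, n) + 1):
        for subset in itertools.combinations(range(n), k):
            res = _circumsphere(pts[list(subset)])
            if res is None:
                continue
            center, radius = res
            tol = radius * 1e-9 + 1e-12
            if np.all(np.linalg.norm(pts - center, axis=1) <= radius + tol):
                if best is None or radius < best[1]:
                    best = (center, radius, pts[list(subset)])
    assert best is not None
    return best


def min_enclosing_sphere(points) -> tuple[np.ndarray, float]:
    """Smallest sphere containing all points: active-set algorithm.

    Maintains a small support set, repeatedly adds the farthest violating
    point and re-solves the small subproblem exactly; converges to tolerance
    1e-9 of the bounding-box diagonal.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if len(pts) == 0:
        raise ValueError("need at least one point")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    bbox_diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    tol = 1e-9 * max(bbox_diag, 1.0)

    # start from the two points extremal along the first principal extent
    start = np.array([pts.argmin(axis=0)[0], pts.argmax(axis=0)[0]])
    active = pts[np.unique(start)]
    for _ in range(10 * len(pts) + 100):
        center, radius, support = _ball_of_support(active)
        dists = np.linalg.norm(pts - center, axis=1)
        worst = int(np.argmax(dists))
        if dists[worst] <= radius + tol:
            return center, radius
        active = np.vstack([support, pts[worst]])
    warnings.warn("min_enclosing_sphere did not converge to tolerance", stacklevel=2)
    return center, float(np.max(np.linalg.norm(pts - center, axis=1)))
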