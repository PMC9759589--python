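"""Tumor shape irregularity (TSI) metrics from a voxel mask.

Seven dimensionless (or size-normalized) descriptors of how far a 3D tumor
model deviates from a sphere:

* sphericity          (36 pi V^2)^(1/3) / A, 1 for a ball
* spherical disproportion   A / (4 pi R^2) with R the equal-volume-sphere
  radius; identically 1/sphericity
* compactness         V / (sqrt(pi) A^(3/2))  ("compactness-1"); equal to
  sphericity^(3/2) / (6 pi), so 1/(6 pi) for a ball
* elongation          sqrt(lambda_minor / lambda_major) of the voxel-center
  second moments
* flatness            sqrt(lambda_least / lambda_major)
* SVR / SVR_N         surface-to-volume ratio A/V (1/cm), and its normalized
  variant SVR * mean principal semi-axis, which removes the 1/r size
  dependence (SVR_N = 3 * 2/sqrt(5) ~= 2.683 for any ball)
* VioS                volumetric index of sphericity: tumor volume over the
  volume of a reference sphere spanning the tumor's maximal extent (default:
  sphere whose diameter is the maximum 3D diameter; alternatively the minimum
  enclosing sphere), 1 for a ball

All area/volume terms come from one marching-cubes mesh and all moment terms
from one eigen-decomposition per mask; conventions are never mixed within a
feature vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .mask_geometry import (
    DegenerateShapeError,
    PrincipalAxes,
    VoxelMask,
    extract_mesh,
    max_3d_diameter,
    mesh_surface_area,
    mesh_volume,
    min_enclosing_sphere,
    principal_axes,
)

CM_PER_MM = 0.1

VIOS_MODES = ("max_diameter", "min_enclosing_sphere")

#: CSV column order used by the CLI and cohort tables.
FEATURE_COLUMNS = [
    "tv_cm3",
    "area_cm2",
    "svr",
    "svr_n",
    "flatness",
    "elongation",
    "spherical_disproportion",
    "compactness",
    "sphericity",
    "vios",
]

#: The seven TSI metrics used as predictors (excludes raw size V, A).
TSI_FEATURES = [
    "svr",
    "svr_n",
    "flatness",
    "elongation",
    "spherical_disproportion",
    "compactness",
    "sphericity",
    "vios",
]


@dataclass
class ShapeFeatureVector:
    volume_cm3: float
    area_cm2: float
    svr: float
    svr_n: float
    flatness: float
    elongation: float
    spherical_disproportion: float
    compactness: float
    sphericity: float
    vios: float

    def to_row(self) -> dict:
        row = asdict(self)
        row["tv_cm3"] = row.pop("volume_cm3")
        row["area_cm2"] = row.pop("area_cm2")
        return {k: row[k] for k in FEATURE_COLUMNS}


def _check_positive(volume_cm3: float, area_cm2: float) -> None:
    if volume_cm3 <= 0 or area_cm2 <= 0:
        raise ValueError("volume and area must be strictly positive")


def sphericity(volume_cm3: float, area_cm2: float) -> float:
    _check_positive(volume_cm3, area_cm2)
    return (36.0 * math.pi * volume_cm3**2) ** (1.0 / 3.0) / area_cm2


def spherical_disproportion(volume_cm3: float, area_cm2: float) -> float:
    _check_positive(volume_cm3, area_cm2)
    radius = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return area_cm2 / (4.0 * math.pi * radius**2)


def compactness(volume_cm3: float, area_cm2: float) -> float:
    _check_positive(volume_cm3, area_cm2)
    return volume_cm3 / (math.sqrt(math.pi) * area_cm2**1.5)


def elongation(axes: PrincipalAxes) -> float:
    if axes.lambda_major <= 0:
        raise DegenerateShapeError("degenerate-shape: zero major moment")
    return math.sqrt(axes.lambda_minor / axes.lambda_major)


def flatness(axes: PrincipalAxes) -> float:
    if axes.lambda_major <= 0:
        raise DegenerateShapeError("degenerate-shape: zero major moment")
    return math.sqrt(axes.lambda_least / axes.lambda_major)


def svr(volume_cm3: float, area_cm2: float) -> float:
    """Surface-to-volume ratio, 1/cm."""
    _check_positive(volume_cm3, area_cm2)
    return area_cm2 / volume_cm3


def svr_n(volume_cm3: float, area_cm2: float, axes: PrincipalAxes) -> float:
    """SVR times the mean principal semi-axis (dimensionless)."""
    mean_semi_axis_cm = float(axes.semi_axes_mm.mean()) * CM_PER_MM
    return svr(volume_cm3, area_cm2) * mean_semi_axis_cm


def vios(mask: VoxelMask, mode: str = "max_diameter") -> float:
    """Volumetric index of sphericity: V_tumor / V_reference_sphere."""
    if mode not in VIOS_MODES:
        raise ValueError(f"vios mode must be one of {VIOS_MODES}")
    mesh = extract_mesh(mask)
    return _vios_from_mesh(mesh_volume(mesh), mesh, mode)


def _vios_from_mesh(volume_cm3: float, mesh, mode: str) -> float:
    if mode == "max_diameter":
        radius_mm = max_3d_diameter(mesh) / 2.0
    else:
        _, radius_mm = min_enclosing_sphere(mesh.vertices)
    if radius_mm <= 0:
        raise DegenerateShapeError("degenerate-shape: zero reference diameter")
    reference_cm3 = (4.0 / 3.0) * math.pi * (radius_mm * CM_PER_MM) ** 3
    return volume_cm3 / reference_cm3


def compute_shape_features(
    mask: VoxelMask, vios_mode: str = "max_diameter"
) -> ShapeFeatureVector:
    """All TSI metrics from one mesh and one moment decomposition."""
    if vios_mode not in VIOS_MODES:
        raise ValueError(f"vios mode must be one of {VIOS_MODES}")
    mesh = extract_mesh(mask)
    volume_cm3 = mesh_volume(mesh)
    area_cm2 = mesh_surface_area(mesh)
    axes = principal_axes(mask)
    return ShapeFeatureVector(
        volume_cm3=volume_cm3,
        area_cm2=area_cm2,
        svr=svr(volume_cm3, area_cm2),
        svr_n=svr_n(volume_cm3, area_cm2, axes),
        flatness=flatness(axes),
        elongation=elongation(axes),
        spherical_disproportion=spherical_disproportion(volume_cm3, area_cm2),
        compactness=compactness(volume_cm3, area_cm2),
        sphericity=sphericity(volume_cm3, area_cm2),
        vios=_vios_from_mesh(volume_cm3, mesh, vios_mode),
    )
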