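"""Shared fixtures: digitized reference solids and a small simulated cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tsiplan import CohortParams, VoxelMask, generate_cohort


def digitized_ellipsoid(semi_axes_mm, spacing=(1.0, 1.0, 1.0), margin_vox=3) -> VoxelMask:
    """Binary mask of a solid ellipsoid centered on the grid."""
    a, b, c = semi_axes_mm
    axes = []
    for half, s in zip((a, b, c), spacing):
        n = int(np.ceil(half / s)) + margin_vox
        axes.append((np.arange(2 * n + 1) - n) * s)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    occ = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    origin = tuple(float(ax[0]) for ax in axes)
    return VoxelMask(occ, spacing, origin)


def digitized_ball(radius_mm, spacing=(1.0, 1.0, 1.0)) -> VoxelMask:
    return digitized_ellipsoid((radius_mm,) * 3, spacing)


def spheroid_surface_area(a: float, b: float) -> float:
    """Closed-form surface area of a prolate spheroid with semi-axes (a, b, b)."""
    e = np.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * np.pi * b**2 * (1.0 + (a / (b * e)) * np.arcsin(e))


@pytest.fixture(scope="session")
def ball10() -> VoxelMask:
    return digitized_ball(10.0)


@pytest.fixture(scope="session")
def ball15() -> VoxelMask:
    return digitized_ball(15.0)


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient imaging cohort reused by the pipeline-level tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortParams(n_patients=30, seed=42))
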