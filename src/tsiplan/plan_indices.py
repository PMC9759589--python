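"""Dose-plan quality indices from a 3D dose grid and a target mask.

Definitions (volumes in cm^3, rx = prescription / margin dose in Gy):

* PIV       volume receiving >= rx
* TV_PIV    volume of target intersected with the PIV
* CI        TV_PIV / TV           (coverage)
* SI        TV_PIV / PIV          (selectivity)
* PCI       TV_PIV^2 / (TV * PIV) = CI * SI   (Paddick conformity)
* GI        V(rx/2) / PIV         (gradient; >= 1, lower is steeper falloff)
* EI        integral dose inside the target over integral dose inside the
            half-prescription isodose region (variant using PIV as the
            denominator region available via ``ei_denominator="piv"``)

Index volumes are voxel-count based (dose and mask share a lattice, so the
systematic digitization bias cancels in the ratios).  Isodose thresholding is
closed (>=) on voxel-center dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .mask_geometry import MM3_PER_CM3, VoxelMask


class UndefinedIndexError(ValueError):
    """Raised when the prescription isodose volume is empty."""


class LatticeMismatchError(ValueError):
    """Raised when dose grid and mask are not on the same lattice."""


@dataclass
class DosePlan:
    """3D absorbed-dose grid (Gy) on a mask's lattice, plus prescription."""

    dose: np.ndarray
    prescription_dose: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shots: list = field(default_factory=list)  # (center mm, sigma mm, weight)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D grid")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.prescription_dose > self.max_dose + 1e-12:
            raise ValueError("prescription dose exceeds maximum dose")

    @property
    def max_dose(self) -> float:
        return float(self.dose.max())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class PlanIndices:
    tv: float
    piv: float
    tv_piv: float
    piv_half: float
    ci: float
    si: float
    pci: float
    gi: float
    ei: float

    def to_dict(self) -> dict:
        return asdict(self)


def isodose_volume(plan: DosePlan, level: float) -> float:
    """Volume (cm^3) of the region with dose >= level (closed threshold)."""
    if level <= 0:
        raise ValueError("isodose level must be positive")
    if level > plan.max_dose:
        warnings.warn(
            f"isodose level {level} Gy exceeds max dose {plan.max_dose:.3g} Gy",
            stacklevel=2,
        )
        return 0.0
    n = int(np.count_nonzero(plan.dose >= level))
    return n * plan.voxel_volume_mm3 / MM3_PER_CM3


def conformity_from_volumes(
    tv: float, piv: float, tv_piv: float, piv_half: float
) -> tuple[float, float, float, float]:
    """(CI, SI, PCI, GI) from the four defining volumes (cm^3)."""
    if piv <= 0:
        raise UndefinedIndexError("prescription isodose volume is empty")
    if tv <= 0:
        raise UndefinedIndexError("target volume is empty")
    ci = tv_piv / tv
    si = tv_piv / piv
    pci = tv_piv**2 / (tv * piv)
    gi = piv_half / piv
    return ci, si, pci, gi


def compute_indices(
    plan: DosePlan, target: VoxelMask, ei_denominator: str = "piv_half"
) -> PlanIndices:
    """All plan-quality indices for a dose grid and target mask."""
    if ei_denominator not in ("piv_half", "piv"):
        raise ValueError("ei_denominator must be 'piv_half' or 'piv'")
    if (
        plan.dose.shape != target.occupancy.shape
        or not np.allclose(plan.spacing, target.spacing)
        or not np.allclose(plan.origin, target.origin)
    ):
        raise LatticeMismatchError("dose grid and mask are not on the same lattice")

    rx = plan.prescription_dose
    vox_cm3 = plan.voxel_volume_mm3 / MM3_PER_CM3
    in_piv = plan.dose >= rx
    in_half = plan.dose >= rx / 2.0
    fg = target.occupancy

    tv = float(fg.sum()) * vox_cm3
    piv = float(in_piv.sum()) * vox_cm3
    tv_piv = float((fg & in_piv).sum()) * vox_cm3
    piv_half = float(in_half.sum()) * vox_cm3
    ci, si, pci, gi = conformity_from_volumes(tv, piv, tv_piv, piv_half)

    target_integral = float(plan.dose[fg].sum()) * vox_cm3
    denom_region = in_half if ei_denominator == "piv_half" else in_piv
    denom_integral = float(plan.dose[denom_region].sum()) * vox_cm3
    ei = target_integral / denom_integral

    return PlanIndices(
        tv=tv, piv=piv, tv_piv=tv_piv, piv_half=piv_half,
        ci=ci, si=si, pci=pci, gi=gi, ei=ei,
    )
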