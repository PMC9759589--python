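"""Synthetic tumors, conformal dose plans, and simulated 2-year cohorts.

Everything the analysis consumes can be generated here, so no patient data is
needed:

* **Tumor masks** — star-shaped solids whose boundary radius is an ellipsoid
  radial function modulated by a zero-mean, band-limited random
  spherical-harmonic field: ``r(theta, phi) = r_ell * (1 + amplitude * s)``
  with ``max|s| = 1``.  Amplitude 0 gives an exact digitized ellipsoid; larger
  amplitudes give lobulated/flat irregular shapes.  An overlapping-spheres
  ("lobes") mode is also available.

* **Dose plans** — a greedy sphere-packing simulator: isotropic Gaussian
  "shots" (default sigmas emulate the 16/8/4 mm collimators, half-maximum
  diameters of 16/8/4 mm) are placed at the in-target voxel farthest from the
  uncovered-region boundary, using the largest collimator whose half-maximum
  radius fits; prescription is the 50% isodose of the resulting maximum dose
  (Gamma Knife convention).  This is a stand-in for real treatment planning
  whose only contract is producing plans with realistic index ranges.

* **Cohorts** — per-patient tables with demographics, Koos grade,
  Gardner-Robertson class, shape features, plan indices, doses, and simulated
  binary 2-year outcomes: growth control depends on margin dose through a
  logistic model (positive dose effect, calibrated to an 85.1% overall control
  rate); hearing preservation is a constant-probability coin (75.9%)
  independent of every covariate, so tumor-shape effects on both outcomes are
  exactly null by construction.

Every output is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq, nnls
from scipy.special import expit, sph_harm_y

from .mask_geometry import MM3_PER_CM3, VoxelMask
from .plan_indices import DosePlan, compute_indices
from .shape_features import compute_shape_features

VOLUME_BOUNDS_CM3 = (0.005, 25.0)

#: sigma (mm) of Gaussian shots emulating the 16/8/4 mm collimators:
#: for a pure Gaussian the half-maximum radius sigma*sqrt(2 ln 2) is 8/4/2 mm.
DEFAULT_COLLIMATOR_SIGMAS = (6.794, 3.397, 1.699)

#: fraction and relative width of the slow "scatter/penumbra" component of a
#: shot profile; a pure Gaussian falls off far more sharply beyond the
#: half-maximum than measured radiosurgery dose profiles do
DEFAULT_TAIL_FRACTION = 0.15
DEFAULT_TAIL_SCALE = 4.0

_R50_FACTOR = math.sqrt(2.0 * math.log(2.0))


def shot_kernel(r2, sigma: float, tail_fraction: float = DEFAULT_TAIL_FRACTION,
                tail_scale: float = DEFAULT_TAIL_SCALE):
    """Radial shot dose profile at squared distance ``r2`` (unit peak)."""
    core = np.exp(-np.asarray(r2) / (2.0 * sigma**2))
    if tail_fraction == 0.0:
        return core
    tail = np.exp(-np.asarray(r2) / (2.0 * (tail_scale * sigma) ** 2))
    return (1.0 - tail_fraction) * core + tail_fraction * tail


def half_maximum_radius(sigma: float, tail_fraction: float = DEFAULT_TAIL_FRACTION,
                        tail_scale: float = DEFAULT_TAIL_SCALE) -> float:
    """Radius (mm) at which a unit shot profile falls to half its peak."""
    if tail_fraction == 0.0:
        return sigma * _R50_FACTOR
    hi = sigma * tail_scale * _R50_FACTOR  # tail alone reaches 0.5*tf beyond this
    return float(
        brentq(lambda r: shot_kernel(r * r, sigma, tail_fraction, tail_scale) - 0.5,
               0.0, hi)
    )


# ---------------------------------------------------------------------------
# tumor mask generation
# ---------------------------------------------------------------------------


@dataclass
class ShapeParams:
    """Parameters of one synthetic tumor shape."""

    base_semi_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)  # mm, a>=b>=c
    perturbation_amplitude: float = 0.0  # in [0, 0.6]
    harmonic_degree_max: int = 6
    lobes: int = 0  # >= 2 switches to overlapping-spheres mode
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    pad_mm: float = 12.0  # grid margin beyond the tumor, for dose falloff
    target_volume_cm3: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        axes = tuple(sorted((float(x) for x in self.base_semi_axes), reverse=True))
        self.base_semi_axes = axes
        if isinstance(self.spacing, (int, float)):
            self.spacing = (float(self.spacing),) * 3
        self.spacing = tuple(float(s) for s in self.spacing)
        if not 0.0 <= self.perturbation_amplitude <= 0.6:
            raise ValueError("perturbation_amplitude must be in [0, 0.6]")
        if any(a <= 0 for a in axes):
            raise ValueError("semi-axes must be positive")


def _fibonacci_directions(n: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of a near-uniform deterministic direction set."""
    i = np.arange(n) + 0.5
    theta = np.arccos(1.0 - 2.0 * i / n)
    phi = np.mod(math.pi * (1.0 + math.sqrt(5.0)) * i, 2.0 * math.pi)
    return theta, phi


class _HarmonicField:
    """Zero-mean band-limited random field on the sphere, max amplitude 1."""

    def __init__(self, degree_max: int, rng: np.random.Generator):
        self.terms = []
        for ell in range(1, degree_max + 1):
            for m in range(-ell, ell + 1):
                coef = rng.normal() + 1j * rng.normal()
                self.terms.append((ell, m, coef))
        theta, phi = _fibonacci_directions()
        raw = self._raw(theta, phi)
        self.norm = float(np.max(np.abs(raw))) or 1.0

    def _raw(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        out = np.zeros_like(theta, dtype=float)
        for ell, m, coef in self.terms:
            out += np.real(coef * sph_harm_y(ell, m, theta, phi))
        return out

    def __call__(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return self._raw(theta, phi) / self.norm


def _ellipsoid_radius(theta, phi, axes) -> np.ndarray:
    a, b, c = axes
    st = np.sin(theta)
    ux, uy, uz = st * np.cos(phi), st * np.sin(phi), np.cos(theta)
    return 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)


def _grid(half_extent_mm: float, spacing) -> tuple[np.ndarray, ...]:
    """Centered world-coordinate axes covering [-half_extent, half_extent]."""
    axes = []
    for s in spacing:
        n = int(math.ceil(2.0 * half_extent_mm / s)) + 1
        coords = (np.arange(n) - (n - 1) / 2.0) * s
        axes.append(coords)
    return tuple(axes)


def generate_tumor_mask(params: ShapeParams) -> VoxelMask:
    """Digitize one synthetic tumor; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    if params.lobes >= 2:
        occ, coords = _lobulated_occupancy(params, rng)
    else:
        occ, coords = _harmonic_occupancy(params, rng)

    # enforce the single-component invariant on the digitized shape
    labels, n = ndimage.label(occ)
    if n > 1:
        sizes = ndimage.sum_labels(occ, labels, index=np.arange(1, n + 1))
        occ = labels == (1 + int(np.argmax(sizes)))
    occ = ndimage.binary_fill_holes(occ)

    origin = tuple(float(c[0]) for c in coords)
    mask = VoxelMask(occ, params.spacing, origin)
    vol = mask.voxel_count_volume_cm3()
    lo, hi = VOLUME_BOUNDS_CM3
    if not lo <= vol <= hi:
        raise ValueError(
            f"generated volume {vol:.4g} cm^3 outside supported range "
            f"[{lo}, {hi}] cm^3; adjust base_semi_axes/target_volume_cm3"
        )
    return mask


def _harmonic_occupancy(params: ShapeParams, rng) -> tuple[np.ndarray, tuple]:
    amp = params.perturbation_amplitude
    field_fn = _HarmonicField(params.harmonic_degree_max, rng) if amp > 0 else None

    axes = np.asarray(params.base_semi_axes, dtype=float)
    scale = 1.0
    if params.target_volume_cm3 is not None:
        # match the continuous shape's volume (direction-grid quadrature of
        # V = (1/3) int r^3 dOmega) to the requested value
        theta, phi = _fibonacci_directions()
        r = _ellipsoid_radius(theta, phi, axes)
        if field_fn is not None:
            r = r * (1.0 + amp * field_fn(theta, phi))
        vol_est = float(np.mean(r**3)) * 4.0 * math.pi / 3.0 / MM3_PER_CM3
        scale = (params.target_volume_cm3 / vol_est) ** (1.0 / 3.0)
    axes = axes * scale

    half_extent = axes[0] * (1.0 + amp) + params.pad_mm
    cx, cy, cz = _grid(half_extent, params.spacing)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    rr = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ell = _ellipsoid_radius(
            np.arccos(np.clip(np.divide(Z, rr, out=np.ones_like(rr), where=rr > 0), -1, 1)),
            np.arctan2(Y, X),
            axes,
        )
    if field_fn is None:
        occ = rr <= r_ell
    else:
        # only voxels in the perturbation shell need the harmonic field
        inside = rr <= r_ell * (1.0 - amp)
        outside = rr > r_ell * (1.0 + amp)
        shell = ~inside & ~outside
        occ = inside.copy()
        if shell.any():
            theta = np.arccos(
                np.clip(np.divide(Z[shell], rr[shell], out=np.ones_like(rr[shell]), where=rr[shell] > 0), -1, 1)
            )
            phi = np.arctan2(Y[shell], X[shell])
            boundary = r_ell[shell] * (1.0 + amp * field_fn(theta, phi))
            occ[shell] = rr[shell] <= boundary
    occ[rr == 0] = True
    return occ, (cx, cy, cz)


def _lobulated_occupancy(params: ShapeParams, rng) -> tuple[np.ndarray, tuple]:
    base = params.base_semi_axes[0]
    radii = base * rng.uniform(0.5, 0.9, size=params.lobes)
    centers = rng.uniform(-0.5 * base, 0.5 * base, size=(params.lobes, 3))
    centers[0] = 0.0  # anchor one lobe at the origin so the union is connected

    def voxelize(radii, centers):
        half_extent = float(np.max(np.linalg.norm(centers, axis=1) + radii)) + params.pad_mm
        cx, cy, cz = _grid(half_extent, params.spacing)
        X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
        occ = np.zeros(X.shape, dtype=bool)
        for r, c in zip(radii, centers):
            occ |= (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
        return occ, (cx, cy, cz)

    occ, coords = voxelize(radii, centers)
    if params.target_volume_cm3 is not None:
        # one corrective rescale of the continuous shape toward the target TV
        vol = occ.sum() * np.prod(params.spacing) / MM3_PER_CM3
        s = (params.target_volume_cm3 / vol) ** (1.0 / 3.0)
        occ, coords = voxelize(radii * s, centers * s)
    return occ, coords


# ---------------------------------------------------------------------------
# sphere-packing dose simulation
# ---------------------------------------------------------------------------


def pack_shots(
    target: VoxelMask,
    collimator_sigmas: tuple[float, ...] = DEFAULT_COLLIMATOR_SIGMAS,
    coverage_goal: float = 0.95,
    max_shots: int = 100,
    margin_dose_gy: float = 12.0,
    spill_factor: float = 1.0,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    tail_scale: float = DEFAULT_TAIL_SCALE,
) -> DosePlan:
    """Greedy Gaussian-shot packing of a target; prescription = 50% of max.

    Shots are placed greedily: each iteration puts the next shot at the
    in-target voxel maximizing the distance to the uncovered-region boundary
    and uses the largest collimator whose half-maximum radius fits that
    distance (a voxel counts as covered once it lies within the half-maximum
    radius of a placed shot).  Packing stops when the covered fraction reaches
    ``coverage_goal`` or at ``max_shots``.  Shot weights are then solved by
    non-negative least squares so that every shot center receives unit summed
    dose — the weight-balancing step that keeps superposition hotspots from
    inflating the maximum dose — and the prescription is set to 50% of the
    resulting maximum (Gamma Knife convention), scaled to ``margin_dose_gy``.
    Deterministic given inputs.
    """
    if target.n_foreground == 0:
        raise ValueError("cannot plan an empty target")
    sigmas = tuple(sorted((float(s) for s in collimator_sigmas), reverse=True))
    spacing = np.asarray(target.spacing)
    occ = target.occupancy
    n_target = occ.sum()

    idx_axes = [np.arange(n) * s for n, s in zip(occ.shape, spacing)]

    # packing runs on the target bounding box; dose is laid on the full grid
    bbox = tuple(
        slice(int(idx.min()), int(idx.max()) + 1)
        for idx in np.nonzero(occ)
    )
    occ_c = occ[bbox]
    crop_axes = [ax[s] for ax, s in zip(idx_axes, bbox)]
    Xc, Yc, Zc = np.meshgrid(*crop_axes, indexing="ij")

    r50s = {s: half_maximum_radius(s, tail_fraction, tail_scale) for s in sigmas}

    centers: list[tuple[float, float, float]] = []
    shot_sigmas: list[float] = []
    covered = np.zeros(occ_c.shape, dtype=bool)
    for _ in range(max_shots):
        uncovered = occ_c & ~covered
        if uncovered.sum() <= (1.0 - coverage_goal) * n_target:
            break
        edt = ndimage.distance_transform_edt(uncovered, sampling=spacing)
        flat = int(np.argmax(edt))
        d = float(edt.flat[flat])
        fitting = [s for s in sigmas if r50s[s] <= spill_factor * d + 1e-9]
        sigma = fitting[0] if fitting else sigmas[-1]
        i, j, k = np.unravel_index(flat, occ_c.shape)
        c = (float(crop_axes[0][i]), float(crop_axes[1][j]), float(crop_axes[2][k]))
        covered |= (Xc - c[0]) ** 2 + (Yc - c[1]) ** 2 + (Zc - c[2]) ** 2 <= r50s[sigma] ** 2
        centers.append(c)
        shot_sigmas.append(float(sigma))

    # weight balancing: unit dose at every shot center (non-negative LS)
    C = np.asarray(centers)
    S = np.asarray(shot_sigmas)
    d2 = ((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    # K[i, j]: dose of a unit shot j at the center of shot i
    kernel = shot_kernel(d2 / S[None, :] ** 2, 1.0, tail_fraction, tail_scale)
    weights, _ = nnls(kernel, np.ones(len(C)))

    dose = np.zeros(occ.shape, dtype=np.float64)
    shots: list[tuple[tuple[float, float, float], float, float]] = []
    gx, gy, gz = idx_axes
    for c, sigma, w in zip(centers, shot_sigmas, weights):
        if w <= 1e-9:
            continue
        # each component is a separable Gaussian: outer product of 1D profiles
        for frac, s in (
            (1.0 - tail_fraction, sigma),
            (tail_fraction, tail_scale * sigma),
        ):
            if frac == 0.0:
                continue
            fx = np.exp(-((gx - c[0]) ** 2) / (2.0 * s**2))
            fy = np.exp(-((gy - c[1]) ** 2) / (2.0 * s**2))
            fz = np.exp(-((gz - c[2]) ** 2) / (2.0 * s**2))
            dose += w * frac * (fx[:, None, None] * fy[None, :, None] * fz[None, None, :])
        world_center = tuple(float(cc + o) for cc, o in zip(c, target.origin))
        shots.append((world_center, float(sigma), float(w)))

    rx = 0.5 * dose.max()
    achieved = float(((dose >= rx) & occ).sum()) / n_target
    if achieved < coverage_goal:
        warnings.warn(
            f"coverage goal {coverage_goal:.2f} not reached with {len(shots)} "
            f"shots (achieved {achieved:.2f})",
            stacklevel=2,
        )
    dose *= margin_dose_gy / rx
    return DosePlan(
        dose=dose,
        prescription_dose=margin_dose_gy,
        spacing=target.spacing,
        origin=target.origin,
        shots=shots,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Study conditions for a simulated vestibular-schwannoma cohort."""

    n_patients: int = 234
    seed: int = 0
    #: target proportions of the three TV strata (<1, 1-5, >5 cm^3)
    stratum_weights: tuple[float, float, float] = (83.0, 89.0, 62.0)
    tv_ranges: tuple = ((0.01, 1.0), (1.0, 5.0), (5.0, 20.01))
    #: margin-dose support and probabilities (Gy); median 12.0
    margin_dose_choices: tuple[float, ...] = (10.5, 11.0, 11.5, 12.0)
    margin_dose_probs: tuple[float, ...] = (0.10, 0.10, 0.15, 0.65)
    #: log-odds of 2-year growth control per Gy of margin dose (> 0)
    beta_dose: float = 0.8
    #: overall 2-year growth-control rate the intercept is calibrated to
    growth_control_rate: float = 0.851
    #: constant 2-year hearing-preservation probability (no covariate effects)
    hearing_preservation_rate: float = 0.759
    #: shape family: uniform amplitude range and axis-ratio range
    amplitude_range: tuple[float, float] = (0.0, 0.5)
    axis_ratio_range: tuple[float, float] = (0.4, 1.0)
    harmonic_degree_max: int = 6
    #: larger tumors draw proportionally smaller irregularity (amplitude and
    #: axis-ratio deviation), reproducing the cohort property that bigger
    #: vestibular schwannomas are more spherical; set False to decouple
    size_dependent_amplitude: bool = True
    #: per-stratum multiplier on irregularity when size-dependence is on
    stratum_irregularity: tuple[float, float, float] = (1.0, 0.7, 0.45)
    female_fraction: float = 131.0 / 234.0
    koos_probs: tuple[float, float, float, float] = (0.142, 0.399, 0.331, 0.128)
    gr_probs: tuple[float, float, float] = (0.210, 0.351, 0.439)  # I, II, III-V
    followup_extra_mean_months: float = 6.0
    followup_max_months: float = 52.0
    coverage_goal: float = 0.95
    max_shots: int = 100
    spill_factor: float = 1.0
    tail_fraction: float = DEFAULT_TAIL_FRACTION
    tail_scale: float = DEFAULT_TAIL_SCALE

    def growth_intercept(self) -> float:
        """Logistic intercept giving the configured overall control rate."""
        doses = np.asarray(self.margin_dose_choices)
        probs = np.asarray(self.margin_dose_probs)
        probs = probs / probs.sum()
        target = self.growth_control_rate

        def mean_rate(b0):
            return float(np.sum(probs * expit(b0 + self.beta_dose * (doses - 12.0)))) - target

        return float(brentq(mean_rate, -10.0, 10.0))


def _spacing_for_tv(tv_cm3: float) -> tuple[float, float]:
    """(isotropic spacing mm, grid pad mm) adapted to the tumor size."""
    if tv_cm3 < 0.2:
        return 0.4, 6.0
    if tv_cm3 < 1.0:
        return 0.6, 8.0
    if tv_cm3 < 5.0:
        return 1.0, 10.0
    return 1.2, 12.0


def sample_shape_params(
    params: CohortParams, tv_cm3: float, stratum: int, seed: int, rng: np.random.Generator
) -> ShapeParams:
    """Draw one tumor's shape parameters from the cohort's shape family."""
    lo, hi = params.amplitude_range
    amp = float(rng.uniform(lo, hi))
    r_lo, r_hi = params.axis_ratio_range
    b_over_a = float(rng.uniform(r_lo, r_hi))
    c_over_b = float(rng.uniform(r_lo, r_hi))
    if params.size_dependent_amplitude:
        mult = params.stratum_irregularity[stratum]
        amp *= mult
        # pull the axis ratios toward 1 by the same factor
        b_over_a = 1.0 - mult * (1.0 - b_over_a)
        c_over_b = 1.0 - mult * (1.0 - c_over_b)
    spacing, pad = _spacing_for_tv(tv_cm3)
    return ShapeParams(
        base_semi_axes=(10.0, 10.0 * b_over_a, 10.0 * b_over_a * c_over_b),
        perturbation_amplitude=amp,
        harmonic_degree_max=params.harmonic_degree_max,
        spacing=(spacing,) * 3,
        pad_mm=pad,
        target_volume_cm3=tv_cm3,
        seed=seed,
    )


def generate_cohort(
    params: CohortParams,
    imaging: bool = True,
    keep_objects: bool = False,
):
    """Simulate a cohort table; optionally also return the masks and plans.

    With ``imaging=False`` the per-patient masks/plans are skipped and the
    shape-feature and plan-index columns are NaN; the demographic, dose, and
    outcome columns (all that the outcome-rate calibration needs) are
    unaffected and identically distributed.
    """
    rng = np.random.default_rng(params.seed)
    weights = np.asarray(params.stratum_weights, dtype=float)
    weights = weights / weights.sum()
    beta0 = params.growth_intercept()
    dose_probs = np.asarray(params.margin_dose_probs, dtype=float)
    dose_probs = dose_probs / dose_probs.sum()

    rows = []
    objects = []
    for pid in range(params.n_patients):
        stratum = int(rng.choice(3, p=weights))
        lo, hi = params.tv_ranges[stratum]
        tv = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        margin_dose = float(rng.choice(params.margin_dose_choices, p=dose_probs))
        row = {
            "id": pid,
            "age": int(rng.integers(18, 90)),
            "sex": "F" if rng.random() < params.female_fraction else "M",
            "koos": int(1 + rng.choice(4, p=np.asarray(params.koos_probs) / sum(params.koos_probs))),
            "gr_class": int(1 + rng.choice(3, p=np.asarray(params.gr_probs) / sum(params.gr_probs))),
            "margin_dose_gy": margin_dose,
            "central_dose_gy": 2.0 * margin_dose,
            "cochlear_dose_gy": float(np.clip(rng.lognormal(math.log(5.6), 0.45), 1.5, 16.1)),
            "cochlea_distance_mm": float(np.clip(rng.exponential(2.6), 0.0, 10.0)),
        }

        shape_seed = int(rng.integers(2**31))
        if imaging:
            sp = sample_shape_params(params, tv, stratum, shape_seed, rng)
            mask = generate_tumor_mask(sp)
            feats = compute_shape_features(mask)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plan = pack_shots(
                    mask,
                    coverage_goal=params.coverage_goal,
                    max_shots=params.max_shots,
                    margin_dose_gy=margin_dose,
                    spill_factor=params.spill_factor,
                    tail_fraction=params.tail_fraction,
                    tail_scale=params.tail_scale,
                )
                idx = compute_indices(plan, mask)
            row.update(feats.to_row())
            row.update({k: v for k, v in idx.to_dict().items()
                        if k in ("ci", "si", "pci", "gi", "ei")})
            row["tv_cm3"] = feats.volume_cm3  # mesh-based TV is the reported TV
            if keep_objects:
                objects.append((mask, plan))
        else:
            row["tv_cm3"] = tv
            for col in ("area_cm2", "svr", "svr_n", "flatness", "elongation",
                        "spherical_disproportion", "compactness", "sphericity",
                        "vios", "ci", "si", "pci", "gi", "ei"):
                row[col] = np.nan

        # outcomes: margin-dose effect on growth control; hearing is a fair
        # constant-rate coin — TSI coefficients are exactly zero by design
        followup = float(min(24.0 + rng.exponential(params.followup_extra_mean_months),
                             params.followup_max_months))
        p_control = float(expit(beta0 + params.beta_dose * (margin_dose - 12.0)))
        growth_event = int(rng.random() > p_control)
        row["growth_event"] = growth_event
        row["growth_time_months"] = (
            _truncated_exponential_time(rng, horizon=24.0) if growth_event else followup
        )
        hearing_eligible = row["gr_class"] in (1, 2)
        row["hearing_eligible"] = int(hearing_eligible)
        if hearing_eligible:
            hearing_event = int(rng.random() > params.hearing_preservation_rate)
            row["hearing_event"] = hearing_event
            row["hearing_time_months"] = (
                _truncated_exponential_time(rng, horizon=24.0) if hearing_event else followup
            )
        else:
            row["hearing_event"] = np.nan
            row["hearing_time_months"] = np.nan
        row["followup_months"] = followup
        rows.append(row)

    df = pd.DataFrame(rows)
    if keep_objects:
        return df, objects
    return df


def _truncated_exponential_time(rng, horizon: float, rate: float = 1.0 / 12.0) -> float:
    """Event time from an exponential conditioned on occurring by ``horizon``."""
    u = rng.random()
    return float(-np.log(1.0 - u * (1.0 - np.exp(-rate * horizon))) / rate)


def write_cohort(outdir: str, params: CohortParams) -> pd.DataFrame:
    """Generate a cohort and write masks/doses (NIfTI), CSV, and manifest."""
    os.makedirs(os.path.join(outdir, "masks"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "doses"), exist_ok=True)
    df, objects = generate_cohort(params, imaging=True, keep_objects=True)
    for pid, (mask, plan) in enumerate(objects):
        mask.to_nifti(os.path.join(outdir, "masks", f"mask_{pid:04d}.nii.gz"))
        affine = np.diag(list(plan.spacing) + [1.0])
        affine[:3, 3] = plan.origin
        import nibabel as nib

        nib.save(nib.Nifti1Image(plan.dose.astype(np.float32), affine),
                 os.path.join(outdir, "doses", f"dose_{pid:04d}.nii.gz"))
    df.to_csv(os.path.join(outdir, "cohort.csv"), index=False)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(asdict(params), fh, indent=2, default=list)
    return df
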