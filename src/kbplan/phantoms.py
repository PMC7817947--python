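"""Synthetic voxel phantoms with a parametric geometry -> dose relationship.

Each phantom holds a spherical planning target (PTV) plus organ-at-risk (OAR)
shapes placed at controlled distances from the PTV surface.  Dose is the
prescription inside the PTV and falls off exponentially with the distance to
the PTV surface outside it,

    D(v) = Rx                        (inside the PTV)
    D(v) = Rx * exp(-lambda * d(v))  (outside, d = distance to PTV surface, mm)

optionally plus Gaussian noise truncated at zero.  Because the DTH -> DVH
relationship is known by construction, every downstream module (histograms,
curve embedding, DVH prediction, objectives, scoring) is testable without
patient data.  The default falloff lambda = 0.06/mm approximates the dose
gradient scale of clinical IMRT; the default lattice is 64^3 voxels at 2 mm.

All randomness flows through explicit integer seeds; there is no global RNG
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_grid import (
    DoseGrid,
    StructureMask,
    VoxelGrid,
    signed_distance_to_surface,
)

__all__ = [
    "OarSpec",
    "PhantomSpec",
    "DoseModelSpec",
    "PhantomCase",
    "generate_case",
    "generate_cohort",
    "scoring_reference_case",
]

DEFAULT_GRID = VoxelGrid(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0))

OarShape = Literal["sphere", "shell", "cylinder"]


@dataclass(frozen=True)
class OarSpec:
    """One OAR: shape plus placement distance from the PTV surface to the OAR
    center (mm, along ``direction``).  ``size_mm`` is the radius for spheres,
    (inner, outer) radius for shells, (radius, half-length) for cylinders."""

    name: str
    distance_mm: float
    size_mm: tuple[float, ...] = (6.0,)
    shape: OarShape = "sphere"
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("OAR size entries must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid = DEFAULT_GRID
    ptv_center_mm: tuple[float, float, float] | None = None
    ptv_radius_mm: float = 10.0
    oars: tuple[OarSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ptv_radius_mm <= 0:
            raise ValueError("ptv radius must be > 0")
        if self.ptv_center_mm is None:
            lo, hi = self.grid.extent()
            object.__setattr__(self, "ptv_center_mm", tuple((lo + hi) / 2.0))


@dataclass(frozen=True)
class DoseModelSpec:
    """Exponential falloff dose model with optional truncated Gaussian noise."""

    prescription_gy: float = 70.0
    falloff_per_mm: float = 0.06
    noise_sd_gy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if self.falloff_per_mm <= 0:
            raise ValueError("falloff constant must be > 0")
        if self.noise_sd_gy < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass
class PhantomCase:
    """Generated case: masks (including ``ptv`` and ``body``), dose, and a
    ground-truth record of the generating parameters."""

    masks: dict[str, StructureMask]
    dose: DoseGrid
    truth: dict

    @property
    def ptv(self) -> StructureMask:
        return self.masks["ptv"]

    @property
    def body(self) -> StructureMask:
        return self.masks["body"]


def _sphere_mask(grid: VoxelGrid, center: np.ndarray, radius: float) -> np.ndarray:
    xx, yy, zz = grid.center_coordinates()
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    return r2 <= radius**2


def _oar_occupancy(grid: VoxelGrid, center: np.ndarray, spec: OarSpec) -> np.ndarray:
    xx, yy, zz = grid.center_coordinates()
    dx, dy, dz = xx - center[0], yy - center[1], zz - center[2]
    if spec.shape == "sphere":
        (r,) = spec.size_mm
        return dx**2 + dy**2 + dz**2 <= r**2
    if spec.shape == "shell":
        r_in, r_out = spec.size_mm
        if r_in >= r_out:
            raise ValueError("shell inner radius must be < outer radius")
        rho2 = dx**2 + dy**2 + dz**2
        return (rho2 >= r_in**2) & (rho2 <= r_out**2)
    if spec.shape == "cylinder":
        r, half_len = spec.size_mm
        return (dx**2 + dy**2 <= r**2) & (np.abs(dz) <= half_len)
    raise ValueError(f"unknown OAR shape {spec.shape!r}")


def _check_inside(grid: VoxelGrid, center: np.ndarray, reach: float, name: str) -> None:
    lo, hi = grid.extent()
    if np.any(center - reach < lo) or np.any(center + reach > hi):
        raise ValueError(f"structure {name!r} extends outside the grid")


def generate_case(
    phantom: PhantomSpec, dose_model: DoseModelSpec
) -> PhantomCase:
    """Build masks and dose for one phantom; deterministic given the seeds.

    The ground-truth record stores the falloff constant, each OAR's placement
    distance, and its noise-free mean dose evaluated from the exact per-voxel
    distance field.
    """
    grid = phantom.grid
    center = np.asarray(phantom.ptv_center_mm, dtype=float)
    _check_inside(grid, center, phantom.ptv_radius_mm, "ptv")
    ptv_occ = _sphere_mask(grid, center, phantom.ptv_radius_mm)
    if not ptv_occ.any():
        raise ValueError("PTV sphere contains no voxel centers")
    ptv = StructureMask(grid=grid, occupancy=ptv_occ, name="ptv", role="target")

    masks: dict[str, StructureMask] = {"ptv": ptv}
    direction_centers: dict[str, np.ndarray] = {}
    for oar in phantom.oars:
        u = np.asarray(oar.direction, dtype=float)
        u = u / np.linalg.norm(u)
        c = center + (phantom.ptv_radius_mm + oar.distance_mm) * u
        reach = max(oar.size_mm)
        _check_inside(grid, c, reach, oar.name)
        occ = _oar_occupancy(grid, c, oar)
        if not occ.any():
            raise ValueError(f"OAR {oar.name!r} contains no voxel centers")
        masks[oar.name] = StructureMask(grid=grid, occupancy=occ, name=oar.name, role="oar")
        direction_centers[oar.name] = c

    body = StructureMask(
        grid=grid,
        occupancy=np.ones(grid.shape, dtype=bool),
        name="body",
        role="external",
    )
    masks["body"] = body

    sd = signed_distance_to_surface(ptv)
    dose_clean = dose_model.prescription_gy * np.exp(
        -dose_model.falloff_per_mm * np.maximum(sd, 0.0)
    )
    dose_values = dose_clean
    if dose_model.noise_sd_gy > 0:
        rng = np.random.default_rng(dose_model.seed)
        dose_values = np.maximum(
            dose_clean + rng.normal(0.0, dose_model.noise_sd_gy, size=grid.shape), 0.0
        )
    dose = DoseGrid(grid=grid, dose=dose_values, prescription=dose_model.prescription_gy)

    truth = {
        "falloff_per_mm": dose_model.falloff_per_mm,
        "prescription_gy": dose_model.prescription_gy,
        "noise_sd_gy": dose_model.noise_sd_gy,
        "oars": {
            oar.name: {
                "distance_mm": oar.distance_mm,
                "mean_dose_noise_free_gy": float(
                    dose_clean[masks[oar.name].occupancy].mean()
                ),
            }
            for oar in phantom.oars
        },
    }
    return PhantomCase(masks=masks, dose=dose, truth=truth)


def generate_cohort(
    n: int,
    distance_range: tuple[float, float] = (8.0, 20.0),
    dose_model: DoseModelSpec = DoseModelSpec(),
    seed: int = 0,
    grid: VoxelGrid = DEFAULT_GRID,
    ptv_radius_mm: float = 10.0,
    oar_radius_mm: float = 6.0,
    oar_name: str = "oar",
) -> list[PhantomCase]:
    """Cohort of single-OAR phantoms with placement distances drawn uniformly
    over ``distance_range``; fully reproducible from ``seed``."""
    if n < 2:
        raise ValueError("a cohort needs n >= 2 cases")
    lo, hi = distance_range
    if not 0 < lo <= hi:
        raise ValueError("distance_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    distances = rng.uniform(lo, hi, size=n)
    noise_seeds = rng.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        spec = PhantomSpec(
            grid=grid,
            ptv_radius_mm=ptv_radius_mm,
            oars=(
                OarSpec(
                    name=oar_name,
                    distance_mm=float(distances[i]),
                    size_mm=(oar_radius_mm,),
                ),
            ),
            seed=seed,
        )
        dm = DoseModelSpec(
            prescription_gy=dose_model.prescription_gy,
            falloff_per_mm=dose_model.falloff_per_mm,
            noise_sd_gy=dose_model.noise_sd_gy,
            seed=int(noise_seeds[i]),
        )
        cases.append(generate_case(spec, dm))
    return cases


def cohort_dataset(
    cases: list[PhantomCase],
    dth_embedding=None,
    t_stage: str = "T2",
    dvh_bin_gy: float = 0.1,
    dth_bin_mm: float = 1.0,
    variance_target: float = 0.97,
    max_components: int = 4,
):
    """Turn phantom cases into model-ready (features, planned DVH) pairs.

    Fits the DTH embedding on these cases when none is given; pass the
    training embedding when preparing held-out cases.  Returns
    ``(dth_embedding, pairs)``.
    """
    from .curve_embedding import fit_embedding
    from .dvh_model import build_features, default_dth_grid
    from .histograms import compute_dth, compute_dvh, resample_curve

    grid = default_dth_grid()
    if dth_embedding is None:
        curves = [
            resample_curve(compute_dth(c.masks["oar"], c.ptv, bin_width=dth_bin_mm), grid)
            for c in cases
        ]
        dth_embedding = fit_embedding(
            curves, variance_target=variance_target, max_components=max_components
        )
    pairs = []
    for c in cases:
        fv = build_features(
            c.masks["oar"], [c.ptv], c.body, dth_embedding,
            t_stage=t_stage, prescription_gy=c.dose.prescription,
            dth_bin_width=dth_bin_mm,
        )
        pairs.append((fv, compute_dvh(c.masks["oar"], c.dose, bin_width=dvh_bin_gy)))
    return dth_embedding, pairs


# structure layout for the full scoring phantom: 3 disjoint target spheres on
# one plane, all Table-style OARs (paired organs as _l/_r) on another.
_SCORING_TARGETS = [("pgtv", 6.0, 70.0), ("ptv1", 11.0, 60.0), ("ptv2", 20.0, 54.0)]
_SCORING_OARS = [
    "brainstem",
    "spinal_cord",
    "optic_chiasm",
    "optic_nerve_l",
    "optic_nerve_r",
    "temporal_lobe_l",
    "temporal_lobe_r",
    "mandible",
    "tmj_l",
    "tmj_r",
    "parotid_l",
    "parotid_r",
    "lens_l",
    "lens_r",
    "pituitary",
    "eye_l",
    "eye_r",
    "inner_ear_l",
    "inner_ear_r",
    "larynx",
    "tongue",
]


def scoring_reference_case() -> tuple[dict[str, StructureMask], DoseGrid, dict[str, float]]:
    """A fully scoreable case with an ideal dose distribution.

    Three disjoint target spheres each receive exactly their prescription
    (70/60/54 Gy) and nothing else receives dose, so every entry of the
    default quality-metric table lands in its best band.  Returns
    ``(masks, dose, prescriptions)``.
    """
    grid = DEFAULT_GRID
    masks: dict[str, StructureMask] = {}
    dose = np.zeros(grid.shape, dtype=float)

    target_x = [24.0, 64.0, 104.0]
    for (name, radius, rx), x in zip(_SCORING_TARGETS, target_x):
        occ = _sphere_mask(grid, np.array([x, 64.0, 30.0]), radius)
        masks[name] = StructureMask(grid=grid, occupancy=occ, name=name, role="target")
        dose[occ] = rx

    # OAR spheres (radius 7 mm -> ~1.4 cc, big enough for D_1cc) on a lattice
    # far from the targets; they receive zero dose.
    slots = [(x, y) for y in (16.0, 40.0, 64.0, 88.0, 112.0) for x in (16.0, 40.0, 64.0, 88.0, 112.0)]
    for name, (x, y) in zip(_SCORING_OARS, slots):
        occ = _sphere_mask(grid, np.array([x, y, 96.0]), 7.0)
        masks[name] = StructureMask(grid=grid, occupancy=occ, name=name, role="oar")

    prescriptions = {name: rx for name, _, rx in _SCORING_TARGETS}
    return masks, DoseGrid(grid=grid, dose=dose, prescription=70.0), prescriptions
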