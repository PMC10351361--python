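"""Synthetic head-and-neck anatomy for adaptive proton therapy simulation.

This module generates voxelized phantoms with the organ set that feeds
head-and-neck toxicity (NTCP) models — two clinical target volumes (CTVs),
parotid glands, superior pharyngeal constrictor, (supraglottic) larynx, oral
cavity, spinal cord, brainstem and esophagus — together with per-fraction
anatomies consisting of a residual rigid setup shift plus a smooth systematic
deformation (parotid/target shrinkage, larynx displacement) whose ground-truth
inverse is stored.  Because the deformation is known exactly, downstream dose
accumulation and NTCP differences are testable without any image registration.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are in mm.
* Displacement fields map planning coordinates to daily coordinates
  (``phi(x) = x + u(x)``); the stored inverse satisfies
  ``phi^-1(y) = y + u_inv(y)``.
* Density is unitless and water-relative (default homogeneous 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError

#: Structure roles every phantom must provide.
ROLES = (
    "CTV_HIGH",
    "CTV_LOW",
    "ORAL_MUCOSA",
    "PAROTID_CONTRA",
    "PAROTID_IPSI",
    "PCM_SUPERIOR",
    "LARYNX_SUPRAGLOTTIC",
    "LARYNX",
    "SPINAL_CORD",
    "BRAINSTEM",
    "ESOPHAGUS",
)

# Reference organ layout for a 128 x 128 x 64 mm volume, as (center, radii) in
# mm relative to the grid center.  The high-risk CTV sits right of midline, so
# "contra" is the left parotid.  Centers/radii are scaled to the actual grid
# extent so that smaller grids host a proportionally smaller anatomy.
_REFERENCE_EXTENT = np.array([128.0, 128.0, 64.0])
_REFERENCE_LAYOUT = {
    "CTV_HIGH": ((12.0, 0.0, 0.0), (14.0, 14.0, 10.0)),
    "CTV_LOW": ((-14.0, 0.0, 0.0), (12.0, 12.0, 9.0)),
    "ORAL_MUCOSA": ((0.0, 26.0, 2.0), (16.0, 10.0, 8.0)),
    "PAROTID_CONTRA": ((-36.0, -8.0, 6.0), (7.0, 9.0, 7.0)),
    "PAROTID_IPSI": ((36.0, -8.0, 6.0), (7.0, 9.0, 7.0)),
    "PCM_SUPERIOR": ((0.0, -18.0, 8.0), (10.0, 4.0, 6.0)),
    "LARYNX_SUPRAGLOTTIC": ((0.0, 10.0, -10.0), (8.0, 6.0, 5.0)),
    "LARYNX": ((0.0, 10.0, -17.0), (10.0, 8.0, 8.0)),
    "SPINAL_CORD": ((0.0, -34.0, 0.0), (5.0, 5.0, 1e9)),
    "BRAINSTEM": ((0.0, -30.0, 24.0), (6.0, 6.0, 8.0)),
    "ESOPHAGUS": ((0.0, -28.0, -24.0), (5.0, 5.0, 8.0)),
}


@dataclass(frozen=True)
class Phantom:
    """A voxelized planning anatomy.

    Attributes
    ----------
    grid_shape : voxels per axis.
    spacing_mm : voxel size per axis (default 2 mm isotropic).
    density : water-relative stopping-power-like scalar per voxel.
    origin_mm : world coordinate of the center of voxel (0, 0, 0).
    """

    grid_shape: tuple[int, int, int]
    spacing_mm: np.ndarray
    density: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "spacing_mm", np.asarray(self.spacing_mm, float))
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float))
        if np.any(self.spacing_mm <= 0):
            raise ConfigurationError("spacing_mm must be > 0 on every axis")
        if self.density.shape != self.grid_shape:
            raise ConfigurationError("density shape does not match grid_shape")
        if np.any(self.density < 0):
            raise ConfigurationError("density must be >= 0 everywhere")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers, one 3-D array per axis."""
        axes = [
            self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.grid_shape[i])
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    @property
    def center_mm(self) -> np.ndarray:
        return self.origin_mm + self.spacing_mm * (np.array(self.grid_shape) - 1) / 2.0

    @property
    def extent_mm(self) -> np.ndarray:
        return self.spacing_mm * np.array(self.grid_shape)


@dataclass
class StructureSet:
    """Named boolean organ masks on a phantom grid."""

    masks: dict[str, np.ndarray]

    def __getitem__(self, role: str) -> np.ndarray:
        if role not in self.masks:
            raise ConfigurationError(f"structure role {role!r} is not present")
        return self.masks[role]

    def get(self, role: str):
        return self.masks.get(role)

    def __contains__(self, role: str) -> bool:
        return role in self.masks

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def validate(self, grid_shape) -> None:
        for role, mask in self.masks.items():
            if mask.shape != tuple(grid_shape):
                raise ConfigurationError(f"mask {role!r} does not match the grid shape")
            if mask.dtype != bool:
                raise ConfigurationError(f"mask {role!r} must be boolean")


@dataclass
class FractionAnatomy:
    """One treatment day: residual setup shift + smooth systematic deformation.

    ``displacement_field_mm`` has shape ``(3, *grid_shape)`` and maps planning
    coordinates to daily coordinates; ``inverse_displacement_mm`` is its
    ground-truth inverse (``x -> phi^-1(x) - x``).
    """

    fraction_index: int  # 1-based
    setup_shift_mm: np.ndarray
    displacement_field_mm: np.ndarray
    inverse_displacement_mm: np.ndarray
    daily_density: np.ndarray
    daily_structures: StructureSet
    spacing_mm: np.ndarray

    @property
    def is_static(self) -> bool:
        """True when this fraction is exactly the planning geometry."""
        return (
            not np.any(self.setup_shift_mm)
            and not np.any(self.displacement_field_mm)
        )


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the simulated trial: 10 patients, 30-35 fractions drawn
    uniformly per patient, 1.5 mm per-axis residual setup error after online
    alignment, and a systematic anatomical drift combining parotid/CTV
    shrinkage with a larynx displacement of larger amplitude than the
    oropharyngeal organs.
    """

    n_patients: int = 10
    n_fractions_range: tuple[int, int] = (30, 35)
    setup_sigma_mm: float = 1.5
    parotid_shrinkage: float = 0.10      # linear contraction at course end
    parotid_medial_drift_mm: float = 0.0  # optional medial centroid drift
    ctv_shrinkage: float = 0.05
    larynx_amplitude_mm: float = 4.0      # displacement envelope at course end
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: float = 2.0
    max_gradient: float = 0.75            # cap on |grad u| (mm per mm); must
                                          # stay < 1 for invertibility
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.n_fractions_range
        if not (1 <= lo <= hi <= 50):
            raise ConfigurationError("n_fractions_range must lie within [1, 50]")
        if self.setup_sigma_mm < 0:
            raise ConfigurationError("setup_sigma_mm must be >= 0")
        if self.spacing_mm <= 0:
            raise ConfigurationError("spacing_mm must be > 0")
        if any(s < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be >= 1 on every axis")
        for name in ("parotid_shrinkage", "ctv_shrinkage"):
            if not (0 <= getattr(self, name) < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.larynx_amplitude_mm < 0:
            raise ConfigurationError("larynx_amplitude_mm must be >= 0")
        if self.parotid_medial_drift_mm < 0:
            raise ConfigurationError("parotid_medial_drift_mm must be >= 0")


def _ellipsoid(phantom: Phantom, center_mm, radii_mm) -> np.ndarray:
    X, Y, Z = phantom.voxel_centers()
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 + ((Z - cz) / rz) ** 2 <= 1.0


def generate_phantom(config: CohortConfig, patient_index: int):
    """Generate one patient's planning phantom and structure set.

    Deterministic given ``(config.random_seed, patient_index)``.  The organ
    layout is an anatomically ordered arrangement of ellipsoids (cylindrical
    spinal cord), jittered per patient, and scaled to the grid extent.  The
    boost CTV and the low-risk CTV are generated DISJOINT (the boost volume is
    subtracted from the low-risk volume) so each target voxel carries a single
    prescription; CTVs never overlap the spinal cord or brainstem.
    """
    config.validate()
    if not (0 <= patient_index < config.n_patients):
        raise ConfigurationError("patient_index out of range for n_patients")

    shape = tuple(int(s) for s in config.grid_shape)
    spacing = np.full(3, float(config.spacing_mm))
    origin = -spacing * (np.array(shape) - 1) / 2.0
    phantom = Phantom(shape, spacing, np.ones(shape), origin)

    scale = phantom.extent_mm / _REFERENCE_EXTENT
    rng = np.random.default_rng((config.random_seed, patient_index, 0))

    masks: dict[str, np.ndarray] = {}
    for role in ROLES:
        center, radii = _REFERENCE_LAYOUT[role]
        center = np.array(center) * scale + phantom.center_mm
        radii = np.array(radii) * np.minimum(scale, 1.0)
        # per-patient variability: a few mm of position jitter, +-10% size
        jitter = rng.uniform(-3.0, 3.0, 3) * np.minimum(scale, 1.0)
        size = rng.uniform(0.9, 1.1, 3)
        finite = radii < 1e8
        masks[role] = _ellipsoid(
            phantom, center + jitter * finite, np.where(finite, radii * size, radii)
        )

    # disjoint targets; targets never overlap the cord or brainstem
    masks["CTV_LOW"] &= ~masks["CTV_HIGH"]
    for ctv in ("CTV_HIGH", "CTV_LOW"):
        masks[ctv] &= ~(masks["SPINAL_CORD"] | masks["BRAINSTEM"])

    for role, mask in masks.items():
        if not mask.any():
            raise ConfigurationError(
                f"grid_shape {shape} is too small to host structure {role!r}"
            )

    structures = StructureSet(masks)
    structures.validate(shape)
    return phantom, structures


def _mask_window(phantom: Phantom, mask: np.ndarray, reach: float = 2.2):
    """Plateau window around a mask, plus its centroid (mm).

    Equal to 1 over the organ itself (so an affine drift acts exactly
    affinely there) and tapered smoothly (cosine-squared) to 0 at ``reach``
    times the organ half-extent, keeping the composite field smooth and
    cheaply invertible.
    """
    X, Y, Z = phantom.voxel_centers()
    pts = np.stack([X[mask], Y[mask], Z[mask]])
    centroid = pts.mean(axis=1)
    half = np.maximum(
        (pts.max(axis=1) - pts.min(axis=1)) / 2.0 + phantom.spacing_mm,
        2.0 * phantom.spacing_mm,
    )
    rho = np.sqrt(
        ((X - centroid[0]) / half[0]) ** 2
        + ((Y - centroid[1]) / half[1]) ** 2
        + ((Z - centroid[2]) / half[2]) ** 2
    )
    t = np.clip((rho - 1.0) / (reach - 1.0), 0.0, 1.0)
    return np.cos(0.5 * np.pi * t) ** 2, centroid


def _sample_vector_field(field: np.ndarray, coords_vox: np.ndarray) -> np.ndarray:
    """Trilinearly sample a (3, ...) field at fractional voxel coordinates."""
    return np.stack(
        [
            ndimage.map_coordinates(field[i], coords_vox, order=1, mode="nearest")
            for i in range(3)
        ]
    )


def invert_displacement(
    field_mm: np.ndarray, spacing_mm: np.ndarray, n_iter: int = 20
) -> np.ndarray:
    """Invert a small smooth displacement field by fixed-point iteration.

    Solves ``u_inv(y) = -u(y + u_inv(y))`` on the voxel grid; converges for
    fields whose gradient is bounded away from 1 (enforced by the generator).
    """
    spacing = np.asarray(spacing_mm, float).reshape(3, 1, 1, 1)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in field_mm.shape[1:]], indexing="ij")
    ).astype(float)
    inv = np.zeros_like(field_mm)
    for _ in range(n_iter):
        coords = idx + inv / spacing
        inv = -_sample_vector_field(field_mm, coords)
    return inv


def _warp_to_daily(volume: np.ndarray, inv_mm: np.ndarray, spacing_mm) -> np.ndarray:
    """Pull a planning-grid volume onto the daily grid using the inverse field."""
    spacing = np.asarray(spacing_mm, float).reshape(3, 1, 1, 1)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in volume.shape], indexing="ij")
    ).astype(float)
    coords = idx + inv_mm / spacing
    return ndimage.map_coordinates(volume.astype(float), coords, order=1, mode="nearest")


def max_displacement_gradient(field_mm: np.ndarray, spacing_mm) -> float:
    """Largest magnitude of any discrete spatial derivative of the field (mm/mm)."""
    spacing = np.asarray(spacing_mm, float)
    worst = 0.0
    for comp in field_mm:
        for axis in range(3):
            if comp.shape[axis] > 1:
                g = np.gradient(comp, spacing[axis], axis=axis)
                worst = max(worst, float(np.abs(g).max()))
    return worst


def generate_fraction_series(
    phantom: Phantom,
    structures: StructureSet,
    config: CohortConfig,
    patient_index: int,
) -> list[FractionAnatomy]:
    """Generate the per-fraction anatomy series for one patient.

    Setup shifts are i.i.d. Gaussian per axis with sigma ``setup_sigma_mm``
    (the residual error left after online rigid alignment).  The systematic
    drift — parotid/boost-CTV shrinkage with a medial parotid centroid drift,
    plus a larger larynx displacement with a spatially sinusoidal profile —
    scales linearly with fraction index, so its magnitude grows monotonically
    over the course.  The exact inverse displacement is stored per fraction.
    """
    config.validate()
    rng = np.random.default_rng((config.random_seed, patient_index, 1))
    lo, hi = config.n_fractions_range
    n_fractions = int(rng.integers(lo, hi + 1))
    shifts = rng.normal(0.0, config.setup_sigma_mm, size=(n_fractions, 3))
    if config.setup_sigma_mm == 0:
        shifts[:] = 0.0

    X, Y, Z = phantom.voxel_centers()
    spacing = phantom.spacing_mm
    mid_x = phantom.center_mm[0]

    # Per-course displacement template (the field at course end); per fraction
    # it is scaled by f / n_fractions.
    template = np.zeros((3,) + phantom.grid_shape)
    drifting = any(
        v > 0
        for v in (
            config.parotid_shrinkage,
            config.parotid_medial_drift_mm,
            config.ctv_shrinkage,
            config.larynx_amplitude_mm,
        )
    )
    if drifting:
        for role in ("PAROTID_CONTRA", "PAROTID_IPSI"):
            window, c = _mask_window(phantom, structures[role])
            medial = -np.sign(c[0] - mid_x) * config.parotid_medial_drift_mm
            template[0] += window * (-config.parotid_shrinkage * (X - c[0]) + medial)
            template[1] += window * (-config.parotid_shrinkage * (Y - c[1]))
            template[2] += window * (-config.parotid_shrinkage * (Z - c[2]))
        window, c = _mask_window(phantom, structures["CTV_HIGH"])
        template[0] += window * (-config.ctv_shrinkage * (X - c[0]))
        template[1] += window * (-config.ctv_shrinkage * (Y - c[1]))
        template[2] += window * (-config.ctv_shrinkage * (Z - c[2]))
        # larynx: anterior-superior displacement whose monotone amplitude
        # envelope carries a smooth (cosine-tapered) spatial profile; the
        # wide window keeps the field curvature low enough to invert to
        # well under a tenth of a voxel
        window, c = _mask_window(phantom, structures["LARYNX"], reach=3.0)
        amp = config.larynx_amplitude_mm * window
        template[1] += amp * 0.6
        template[2] += amp * 0.8

        grad = max_displacement_gradient(template, spacing)
        if grad > config.max_gradient:
            raise ConfigurationError(
                "drift parameters produce a displacement gradient of "
                f"{grad:.2f} mm/mm, above max_gradient={config.max_gradient}"
            )

    series: list[FractionAnatomy] = []
    for f in range(1, n_fractions + 1):
        s = f / n_fractions
        u = template * s
        static = not (np.any(u) or np.any(shifts[f - 1]))
        if static:
            inv = np.zeros_like(u)
            daily_density = phantom.density.copy()
            daily_masks = {r: m.copy() for r, m in structures.masks.items()}
        else:
            inv = invert_displacement(u, spacing)
            daily_density = _warp_to_daily(phantom.density, inv, spacing)
            daily_masks = {
                r: _warp_to_daily(m, inv, spacing) >= 0.5
                for r, m in structures.masks.items()
            }
        series.append(
            FractionAnatomy(
                fraction_index=f,
                setup_shift_mm=shifts[f - 1].copy(),
                displacement_field_mm=u,
                inverse_displacement_mm=inv,
                daily_density=daily_density,
                daily_structures=StructureSet(daily_masks),
                spacing_mm=spacing.copy(),
            )
        )
    return series
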