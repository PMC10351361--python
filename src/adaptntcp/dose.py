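"""Analytic spot-based proton dose engine.

A deliberately simple pencil-beam model that produces dose-influence matrices
with the qualitative features that matter for adaptive-planning logic: a
single-peaked Bragg curve whose maximum sits at the nominal water-equivalent
range, a lateral Gaussian that broadens with depth, and exact linearity of
dose in the spot weights.  Doses are in Gy(RBE) per unit spot weight with the
constant proton RBE of 1.1 already folded in.

The beam geometry is a parallel beam in the axial (x, y) plane: a gantry
angle of 0 deg means the beam enters from anterior (+y) and travels toward
-y; angles increase clockwise when viewed from superior.  Beam's-eye-view
(BEV) lateral coordinates are (u, z) with u the in-plane axis perpendicular
to the beam and z the patient superior-inferior axis.

A rigid setup shift is modeled as an isocenter translation.  For a parallel
beam only the component of the shift perpendicular to the beam axis changes
the dose: the water-equivalent depth of a voxel is measured from the patient
surface, which translates with the patient, so the along-beam component
cancels exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .anatomy import Phantom
from .errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

RBE = 1.1

#: 1-sigma width (mm) of the distal Gaussian falloff of the Bragg curve.
FALLOFF_MM = 1.0
#: 1-sigma width (mm) of the proximal shoulder of the Bragg peak.
_PROXIMAL_MM = 3.0
#: Entrance plateau level relative to the unit peak Gaussian.
_PLATEAU = 0.30


@dataclass(frozen=True)
class Spot:
    """One scanned pencil beam (beamlet)."""

    beam_angle_deg: float
    lateral_position_mm: tuple[float, float]  # (u, z) in BEV
    nominal_range_mm: float
    spot_id: int

    def __post_init__(self):
        if not 0 <= self.beam_angle_deg < 360:
            raise ConfigurationError("beam_angle_deg must lie in [0, 360)")
        if self.nominal_range_mm <= 0:
            raise ConfigurationError("nominal_range_mm must be > 0")


@dataclass
class SpotSet:
    """An ordered spot list with its (unitless, non-negative) weight vector."""

    spots: list[Spot]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.spots):
            raise ConfigurationError("weight vector length must equal spot count")
        if np.any(self.weights < 0):
            raise DomainError("spot weights must be >= 0")
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("spot_ids must be unique")

    def __len__(self) -> int:
        return len(self.spots)

    def with_weights(self, weights: np.ndarray) -> "SpotSet":
        return SpotSet(self.spots, np.asarray(weights, float).copy())


@dataclass
class InfluenceMatrix:
    """Sparse dose operator: ``matrix[i, j]`` = Gy(RBE) to voxel i per unit
    weight of spot j, flattened in C order over the phantom grid."""

    matrix: sparse.csc_matrix
    grid_shape: tuple[int, int, int]
    spacing_mm: np.ndarray
    setup_shift_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[1]


def beam_axes(angle_deg: float):
    """Unit vectors (propagation d, lateral e_u) of a gantry angle, in (x, y)."""
    a = np.deg2rad(angle_deg)
    # source sits at angle a on the anterior circle: s = (sin a, cos a)
    d = np.array([-np.sin(a), -np.cos(a), 0.0])
    e_u = np.array([np.cos(a), -np.sin(a), 0.0])
    return d, e_u


def depth_dose(range_mm: float, depth_mm) -> np.ndarray | float:
    """Integral depth-dose of a single pencil beam (per unit weight).

    A flat-ish entrance plateau cut off sigmoidally at the range, plus an
    asymmetric Gaussian peak (proximal sigma 3 mm, distal sigma
    ``FALLOFF_MM``) centered at the nominal range.  Single-peaked with its
    maximum within a voxel of ``range_mm``; falls below 1% of the peak beyond
    ``range_mm + 5 * FALLOFF_MM``.
    """
    if range_mm <= 0:
        raise DomainError("range_mm must be > 0")
    depth = np.asarray(depth_mm, float)
    if np.any(depth < 0):
        raise DomainError("depth_mm must be >= 0")
    z = depth - range_mm
    sigma = np.where(z < 0, _PROXIMAL_MM, FALLOFF_MM)
    peak = np.exp(-0.5 * (z / sigma) ** 2)
    plateau = _PLATEAU * (1.0 + 0.4 * np.minimum(depth / range_mm, 1.0))
    cutoff = 1.0 / (1.0 + np.exp(np.clip(z / FALLOFF_MM, -60, 60)))
    out = RBE * (plateau * cutoff + peak)
    return out if out.shape else float(out)


def lateral_sigma(depth_mm, sigma0_mm: float = 3.0, k: float = 0.02):
    """Lateral Gaussian sigma of a pencil beam as a function of depth."""
    return sigma0_mm + k * np.asarray(depth_mm, float)


def _wed_map(phantom: Phantom, angle_deg: float) -> np.ndarray:
    """Water-equivalent depth of every voxel for one beam angle.

    For a homogeneous phantom this is the exact analytic ray-box path length
    times the density; for a heterogeneous one the density is rotated so the
    beam runs along an array axis, integrated cumulatively, and rotated back.
    """
    d, _ = beam_axes(angle_deg)
    density = phantom.density
    if np.ptp(density) == 0:
        X, Y, _ = phantom.voxel_centers()
        lo = phantom.origin_mm - phantom.spacing_mm / 2.0
        hi = lo + phantom.extent_mm
        t_entry = np.full(phantom.grid_shape, np.inf)
        for axis, coord in ((0, X), (1, Y)):
            if abs(d[axis]) > 1e-12:
                bound = lo[axis] if d[axis] > 0 else hi[axis]
                t_entry = np.minimum(t_entry, (coord - bound) / d[axis])
        return float(density.flat[0]) * np.maximum(t_entry, 0.0)

    # heterogeneous: rotate so the beam propagates along +x (axis 0);
    # ndimage.rotate(angle, axes=(1, 0)) rotates vectors CCW in the (x, y)
    # index plane, so the beam direction maps onto +x for angle -atan2(dy, dx).
    # Pad to the in-plane diagonal first so no material crops off under
    # rotation (reshape=False keeps the array shape fixed).
    ang = -np.degrees(np.arctan2(d[1], d[0]))
    nx, ny = density.shape[:2]
    half = (int(np.ceil(np.hypot(nx, ny))) - min(nx, ny)) // 2 + 1
    padded = np.pad(density, ((half, half), (half, half), (0, 0)))
    rot = ndimage.rotate(
        padded, ang, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
    )
    step = phantom.spacing_mm[0]
    wed_rot = (np.cumsum(rot, axis=0) - 0.5 * rot) * step
    wed = ndimage.rotate(
        wed_rot, -ang, axes=(1, 0), reshape=False, order=1, mode="nearest"
    )[half:half + nx, half:half + ny]
    return np.maximum(wed, 0.0)


def compute_influence(
    phantom: Phantom,
    spots: SpotSet,
    setup_shift_mm=(0.0, 0.0, 0.0),
    *,
    cutoff_rel: float = 1e-4,
    sigma0_mm: float = 3.0,
    sigma_k: float = 0.02,
    lateral_truncation: float = 3.5,
) -> InfluenceMatrix:
    """Compute the dose-influence matrix of a spot set on a phantom.

    Each column is ``depth_dose`` along the spot's ray (water-equivalent depth
    from the density line integral) times a depth-broadened lateral Gaussian,
    truncated at ``lateral_truncation`` sigma and thresholded at
    ``cutoff_rel`` of the per-column maximum (the sparsity cutoff slightly
    perturbs dose-conservation checks).  Deterministic; a spot whose ray
    misses the grid yields a zero column and a logged warning.
    """
    if len(spots) == 0:
        raise ConfigurationError("spots must be non-empty")
    shift = np.asarray(setup_shift_mm, float)
    X, Y, Z = phantom.voxel_centers()
    iso = phantom.center_mm

    n_vox = phantom.n_voxels
    cols_i: list[np.ndarray] = [None] * len(spots)
    cols_v: list[np.ndarray] = [None] * len(spots)

    by_angle: dict[float, list[int]] = {}
    for j, sp in enumerate(spots.spots):
        by_angle.setdefault(sp.beam_angle_deg, []).append(j)

    for angle, idxs in by_angle.items():
        _, e_u = beam_axes(angle)
        # BEV lateral coordinates of every voxel; the setup shift enters as a
        # pure lateral offset (see module docstring)
        u = (
            (X - iso[0] + shift[0]) * e_u[0] + (Y - iso[1] + shift[1]) * e_u[1]
        ).ravel()
        zc = (Z - iso[2] + shift[2]).ravel()
        wed = _wed_map(phantom, angle).ravel()
        sig = lateral_sigma(wed, sigma0_mm, sigma_k)
        trunc2 = (lateral_truncation * sig) ** 2
        for j in idxs:
            sp = spots.spots[j]
            us, zs = sp.lateral_position_mm
            r2 = (u - us) ** 2 + (zc - zs) ** 2
            cand = np.flatnonzero(r2 <= trunc2)
            if cand.size == 0:
                log.warning("spot %d (angle %g) misses the dose grid", sp.spot_id, angle)
                cols_i[j] = np.empty(0, int)
                cols_v[j] = np.empty(0, float)
                continue
            s = sig[cand]
            vals = depth_dose(sp.nominal_range_mm, wed[cand]) * np.exp(
                -0.5 * r2[cand] / s**2
            ) / (2.0 * np.pi * s**2)
            keep = vals > cutoff_rel * vals.max() if vals.size else slice(0)
            cols_i[j] = cand[keep]
            cols_v[j] = vals[keep]
            if cols_v[j].size == 0:
                log.warning("spot %d (angle %g) misses the dose grid", sp.spot_id, angle)

    indptr = np.zeros(len(spots) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([c.size for c in cols_i])
    indices = np.concatenate(cols_i) if cols_i else np.empty(0, int)
    data = np.concatenate(cols_v) if cols_v else np.empty(0, float)
    matrix = sparse.csc_matrix((data, indices, indptr), shape=(n_vox, len(spots)))
    return InfluenceMatrix(matrix, phantom.grid_shape, phantom.spacing_mm.copy(), shift)


def compute_dose(influence: InfluenceMatrix, weights: np.ndarray) -> np.ndarray:
    """Dose grid (Gy(RBE), 3-D array) from an influence matrix and weights.

    Exactly linear and homogeneous in the weights.
    """
    w = np.asarray(weights, float)
    if w.ndim != 1 or w.size != influence.n_spots:
        raise ConfigurationError("weight vector length must equal spot count")
    if np.any(w < 0):
        raise DomainError("spot weights must be >= 0")
    return np.asarray(influence.matrix @ w).reshape(influence.grid_shape)
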