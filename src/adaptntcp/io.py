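"""Persistence: volumes as NIfTI, plans as JSON, reports as CSV.

Volumes (density, masks, dose grids) are stored one file per volume as
uncompressed NIfTI with the voxel spacing and origin in the header; fraction
metadata (setup shifts, seeds) travels in JSON sidecars.  Plans serialize to
JSON (spots + weights + robustness + a provenance hash of the phantom).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .anatomy import Phantom, StructureSet
from .dose import InfluenceMatrix, Spot, SpotSet
from .planning import Plan, RobustnessSetting


def save_volume(path, array: np.ndarray, spacing_mm, origin_mm) -> None:
    affine = np.diag(list(np.asarray(spacing_mm, float)) + [1.0])
    affine[:3, 3] = np.asarray(origin_mm, float)
    nib.save(nib.Nifti1Image(np.asarray(array, np.float32), affine), str(path))


def load_volume(path):
    img = nib.load(str(path))
    affine = img.affine
    return (
        np.asarray(img.dataobj, float),
        np.diag(affine)[:3].copy(),
        affine[:3, 3].copy(),
    )


def phantom_hash(phantom: Phantom) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(phantom.density).tobytes())
    h.update(phantom.spacing_mm.tobytes())
    h.update(phantom.origin_mm.tobytes())
    return h.hexdigest()[:16]


def save_phantom(outdir, phantom: Phantom, structures: StructureSet) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(outdir / "density.nii", phantom.density,
                phantom.spacing_mm, phantom.origin_mm)
    for role, mask in structures.masks.items():
        save_volume(outdir / f"mask_{role}.nii", mask,
                    phantom.spacing_mm, phantom.origin_mm)
    meta = {
        "grid_shape": list(phantom.grid_shape),
        "spacing_mm": phantom.spacing_mm.tolist(),
        "origin_mm": phantom.origin_mm.tolist(),
        "roles": list(structures.roles),
        "hash": phantom_hash(phantom),
    }
    (outdir / "phantom.json").write_text(json.dumps(meta, indent=1))


def load_phantom(indir):
    indir = Path(indir)
    meta = json.loads((indir / "phantom.json").read_text())
    density, spacing, origin = load_volume(indir / "density.nii")
    phantom = Phantom(tuple(meta["grid_shape"]), spacing, density, origin)
    masks = {}
    for role in meta["roles"]:
        vol, _, _ = load_volume(indir / f"mask_{role}.nii")
        masks[role] = vol >= 0.5
    return phantom, StructureSet(masks)


def save_plan(path, plan: Plan, phantom: Phantom | None = None) -> None:
    doc = {
        "spots": [
            {
                "beam_angle_deg": s.beam_angle_deg,
                "lateral_position_mm": list(s.lateral_position_mm),
                "nominal_range_mm": s.nominal_range_mm,
                "spot_id": s.spot_id,
            }
            for s in plan.spots.spots
        ],
        "weights": plan.weights.tolist(),
        "robustness": {
            "setup_uncertainty_mm": plan.robustness.setup_uncertainty_mm,
            "scenario_shifts": [s.tolist() for s in plan.robustness.scenario_shifts],
        },
        "objective_value": plan.objective_value,
        "converged": plan.converged,
        "phantom_hash": phantom_hash(phantom) if phantom is not None else None,
    }
    Path(path).write_text(json.dumps(doc))


def load_plan(path) -> Plan:
    doc = json.loads(Path(path).read_text())
    spots = [
        Spot(s["beam_angle_deg"], tuple(s["lateral_position_mm"]),
             s["nominal_range_mm"], s["spot_id"])
        for s in doc["spots"]
    ]
    robustness = RobustnessSetting(
        doc["robustness"]["setup_uncertainty_mm"],
        [np.asarray(s) for s in doc["robustness"]["scenario_shifts"]],
    )
    return Plan(
        SpotSet(spots, np.asarray(doc["weights"], float)),
        robustness,
        doc["objective_value"],
        [],
        doc["converged"],
    )


def save_influence(path_mtx, influence: InfluenceMatrix) -> None:
    """Influence matrix as Matrix Market with a JSON geometry sidecar."""
    path_mtx = Path(path_mtx)
    spio.mmwrite(str(path_mtx), influence.matrix)
    sidecar = {
        "grid_shape": list(influence.grid_shape),
        "spacing_mm": influence.spacing_mm.tolist(),
        "setup_shift_mm": influence.setup_shift_mm.tolist(),
    }
    path_mtx.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_influence(path_mtx) -> InfluenceMatrix:
    path_mtx = Path(path_mtx)
    matrix = sparse.csc_matrix(spio.mmread(str(path_mtx)))
    meta = json.loads(path_mtx.with_suffix(".json").read_text())
    return InfluenceMatrix(
        matrix,
        tuple(meta["grid_shape"]),
        np.asarray(meta["spacing_mm"]),
        np.asarray(meta["setup_shift_mm"]),
    )


def write_cohort_outputs(outdir, cohort: dict) -> None:
    """CSV exports of a :func:`adaptntcp.pipeline.run_cohort` result."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# combination rule: {cohort['combination_rule']}\n"
    for name, frame in (
        ("ntcp_by_scenario", cohort["ntcp_by_scenario"]),
        ("delta_ntcp", cohort["per_patient"]),
        ("total_reductions", cohort["totals"]),
        ("cohort_summary", cohort["summary"]),
        ("verdicts", cohort["verdicts"]),
    ):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    (outdir / "significance_counts.json").write_text(
        json.dumps(cohort["significance_counts"], indent=1)
    )
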