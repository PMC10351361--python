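"""Dose-volume metrics, gEUD and NTCP models for six head-and-neck toxicities.

The shipped model registry covers:

========================  =======================  ==============================
endpoint                  model family             inputs
========================  =======================  ==============================
oral_mucositis            logistic in D/D50        Dmean oral mucosa (D50=51, k=1)
xerostomia                probit in gEUD           gEUD(n=1) contralateral parotid
                                                   (D50=39.9 Gy, m=0.4)
swallow_solids            multivariable logistic   X1=Dmean supraglottic larynx,
                                                   X2=1 (a=5.98, b=0.074, c=-1.209)
swallow_liquids           multivariable logistic   X1=Dmean superior PCM, X2=Dmean
                                                   supraglottic larynx
                                                   (a=6.89, b=0.049, c=0.048)
dysphagia                 multivariable logistic   same X1/X2 (a=6.09, b=0.057,
                                                   c=0.037)
aspiration                probit in gEUD           gEUD(n=1) larynx
                                                   (D50=46.5 Gy, m=0.5)
========================  =======================  ==============================

All NTCP values are unit-interval probabilities internally; exports convert
to percent.  Metrics feeding the models are computed on the exact voxel-dose
empirical distribution (no binning); a binned cumulative DVH curve is kept
only for export and plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import ndtr  # standard normal CDF

from .anatomy import ROLES, StructureSet
from .errors import ConfigurationError, DomainError

ENDPOINTS = (
    "oral_mucositis",
    "xerostomia",
    "swallow_solids",
    "swallow_liquids",
    "dysphagia",
    "aspiration",
)

#: The four endpoints derived from distinct anatomical structures that enter
#: the any-of-four total toxicity probability.
MAIN_ENDPOINTS = ("xerostomia", "dysphagia", "aspiration", "oral_mucositis")


@dataclass
class DVHMetrics:
    """Exact-distribution dose statistics of one structure."""

    dmean: float
    dmax: float
    d2: float
    d98: float
    curve_dose_gy: np.ndarray
    curve_volume_frac: np.ndarray


def d_percent(dose_values: np.ndarray, p: float) -> float:
    """D_p%: the smallest voxel dose ``d`` such that the fraction of the
    structure receiving at least ``d`` is at most ``p/100``.

    Ties matter: when the candidate dose repeats across the cutoff index the
    next strictly greater attained dose is the smallest one satisfying the
    definition.  If no attained dose satisfies it, the maximum is returned.
    """
    v = np.sort(np.asarray(dose_values, float))
    n = v.size
    k = min(max(math.ceil(n * (100.0 - p) / 100.0 - 1e-9), 0), n - 1)
    if np.searchsorted(v, v[k], side="left") >= k:
        return float(v[k])
    j = int(np.searchsorted(v, v[k], side="right"))
    return float(v[min(j, n - 1)])


def dvh_metrics(dose: np.ndarray, mask: np.ndarray, bin_gy: float = 0.1):
    """DVH metrics of ``dose`` inside ``mask``; ``None`` when the mask is
    empty (the structure is not evaluable, not an error)."""
    m = np.asarray(mask, bool)
    if not m.any():
        return None
    d = np.asarray(dose, float)[m]
    edges = np.arange(0.0, d.max() + 2 * bin_gy, bin_gy)
    frac = 1.0 - np.searchsorted(np.sort(d), edges, side="left") / d.size
    return DVHMetrics(
        dmean=float(d.mean()),
        dmax=float(d.max()),
        d2=d_percent(d, 2.0),
        d98=d_percent(d, 98.0),
        curve_dose_gy=edges,
        curve_volume_frac=frac,
    )


def geud(dose: np.ndarray, mask: np.ndarray, n: float) -> float:
    """Generalized equivalent uniform dose: power mean with exponent ``1/n``
    over equal-volume voxels.  ``n = 1`` is exactly the mean dose; an all-zero
    dose returns 0 for any ``n``."""
    if n == 0:
        raise DomainError("gEUD volume parameter n must be nonzero")
    m = np.asarray(mask, bool)
    if not m.any():
        raise DomainError("gEUD of an empty mask is undefined")
    d = np.asarray(dose, float)[m]
    if not d.any():
        return 0.0
    if n == 1:
        return float(d.mean())
    return float(np.mean(d ** (1.0 / n)) ** n)


def ntcp_logistic_d50k(D: float, D50: float, k: float) -> float:
    """Logistic dose response ``(1 + (D50/D)^k)^-1``; 0 at ``D = 0`` by
    continuity."""
    if D < 0 or D50 <= 0:
        raise DomainError("require D >= 0 and D50 > 0")
    if D == 0:
        return 0.0
    return float(1.0 / (1.0 + (D50 / D) ** k))


def ntcp_probit_geud(geud_gy: float, D50: float, m: float) -> float:
    """Probit (Lyman-type) response ``Phi((gEUD - D50) / (m * D50))``."""
    if m <= 0 or D50 <= 0:
        raise DomainError("require m > 0 and D50 > 0")
    return float(ndtr((geud_gy - D50) / (m * D50)))


def ntcp_multivar_logistic(X1: float, X2: float, a: float, b: float, c: float) -> float:
    """Multivariable logistic response ``(1 + exp(a - b*X1 - c*X2))^-1``."""
    if not (np.isfinite(X1) and np.isfinite(X2)):
        raise DomainError("X1 and X2 must be finite")
    s = a - b * X1 - c * X2
    return float(1.0 / (1.0 + math.exp(min(s, 700.0))))


@dataclass
class NTCPModelSpec:
    """One registry row: endpoint, model family, structure inputs, parameters."""

    endpoint: str
    family: str  # logistic_d50k | probit_geud | multivar_logistic
    structures: list[str]
    params: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.family not in ("logistic_d50k", "probit_geud", "multivar_logistic"):
            raise ConfigurationError(f"unknown NTCP model family {self.family!r}")
        p = self.params
        if self.family == "logistic_d50k" and p.get("D50", 1.0) <= 0:
            raise ConfigurationError("D50 must be > 0")
        if self.family == "probit_geud":
            if p.get("D50", 1.0) <= 0 or p.get("m", 1.0) <= 0 or p.get("n", 1.0) == 0:
                raise ConfigurationError("probit model requires D50 > 0, m > 0, n != 0")


def default_registry() -> list[NTCPModelSpec]:
    """The six shipped head-and-neck toxicity models."""
    return [
        NTCPModelSpec("oral_mucositis", "logistic_d50k", ["ORAL_MUCOSA"],
                      {"D50": 51.0, "k": 1.0}),
        NTCPModelSpec("xerostomia", "probit_geud", ["PAROTID_CONTRA"],
                      {"D50": 39.9, "m": 0.4, "n": 1.0}),
        NTCPModelSpec("swallow_solids", "multivar_logistic", ["LARYNX_SUPRAGLOTTIC"],
                      {"a": 5.98, "b": 0.074, "c": -1.209, "X2": 1.0}),
        NTCPModelSpec("swallow_liquids", "multivar_logistic",
                      ["PCM_SUPERIOR", "LARYNX_SUPRAGLOTTIC"],
                      {"a": 6.89, "b": 0.049, "c": 0.048}),
        NTCPModelSpec("dysphagia", "multivar_logistic",
                      ["PCM_SUPERIOR", "LARYNX_SUPRAGLOTTIC"],
                      {"a": 6.09, "b": 0.057, "c": 0.037}),
        NTCPModelSpec("aspiration", "probit_geud", ["LARYNX"],
                      {"D50": 46.5, "m": 0.5, "n": 1.0}),
    ]


def shipped_registry_path():
    """Path of the versioned YAML registry distributed with the package
    (identical in content to :func:`default_registry`)."""
    from importlib import resources

    return resources.files("adaptntcp") / "data" / "ntcp_models.yaml"


def registry_to_yaml(registry: list[NTCPModelSpec], path) -> None:
    rows = [
        {"endpoint": r.endpoint, "family": r.family,
         "structures": list(r.structures), "params": dict(r.params)}
        for r in registry
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"version": 1, "models": rows}, fh, sort_keys=False)


def registry_from_yaml(path) -> list[NTCPModelSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [
        NTCPModelSpec(r["endpoint"], r["family"], list(r["structures"]),
                      {k: float(v) for k, v in r["params"].items()})
        for r in doc["models"]
    ]


@dataclass
class ScenarioNTCP:
    """Per-endpoint NTCP of one accumulated dose distribution.

    ``values[endpoint]`` is a unit-interval probability, or ``None`` with the
    reason recorded in ``not_evaluable`` (absent structure, or structure fully
    engulfed by the target volumes — its model no longer measures an
    organ-at-risk effect).  Not-evaluable propagates downstream as missing,
    never as zero.
    """

    label: str
    values: dict[str, float | None]
    metrics: dict[str, DVHMetrics]
    not_evaluable: dict[str, str] = field(default_factory=dict)


def _model_value(spec: NTCPModelSpec, inputs: list[float]) -> float:
    p = spec.params
    if spec.family == "logistic_d50k":
        return ntcp_logistic_d50k(inputs[0], p["D50"], p["k"])
    if spec.family == "probit_geud":
        return ntcp_probit_geud(inputs[0], p["D50"], p["m"])
    x1 = inputs[0]
    x2 = p.get("X2", inputs[1] if len(inputs) > 1 else 0.0)
    return ntcp_multivar_logistic(x1, x2, p["a"], p["b"], p["c"])


def evaluate_all(
    dose: np.ndarray,
    structures: StructureSet,
    registry: list[NTCPModelSpec] | None = None,
    label: str = "",
) -> ScenarioNTCP:
    """Evaluate every registry model on an accumulated planning-grid dose."""
    registry = registry if registry is not None else default_registry()
    known = set(ROLES) | set(structures.roles)
    target = np.zeros(dose.shape, bool)
    for ctv in ("CTV_HIGH", "CTV_LOW"):
        if ctv in structures:
            target |= structures[ctv]

    values: dict[str, float | None] = {}
    metrics: dict[str, DVHMetrics] = {}
    not_evaluable: dict[str, str] = {}
    for spec in registry:
        spec.validate()
        inputs = []
        reason = None
        for role in spec.structures:
            if role not in known:
                raise ConfigurationError(
                    f"NTCP registry references unknown structure role {role!r}"
                )
            mask = structures.get(role)
            if mask is None:
                reason = f"structure {role} absent"
                break
            if not mask.any():
                reason = f"structure {role} empty"
                break
            if np.array_equal(mask & target, mask):
                reason = f"structure {role} fully encompassed by the target volumes"
                break
            if role not in metrics:
                metrics[role] = dvh_metrics(dose, mask)
            if spec.family == "probit_geud":
                inputs.append(geud(dose, mask, spec.params.get("n", 1.0)))
            else:
                inputs.append(metrics[role].dmean)
        if reason is not None:
            values[spec.endpoint] = None
            not_evaluable[spec.endpoint] = reason
        else:
            values[spec.endpoint] = _model_value(spec, inputs)
    return ScenarioNTCP(label, values, metrics, not_evaluable)
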