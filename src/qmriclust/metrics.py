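"""Estimator construction and group difference maps.

The per-voxel estimator E is either a single quantitative parameter (T1,
T2*, FW — used as-is, in their native units) or the joint metric

    E_joint = s_FW * FW/n_FW + s_T1 * T1/n_T1 + s_T2* * T2*/n_T2*

where each normalization factor n_m is the CSF value of that modality, so
all three terms are dimensionless and of order one.  Because FW is already
expressed in percent of CSF, its normalized term is close to 1 and carries
the largest weight; T1 and T2* act as contrast-enhancing factors.  The
signs s_m are chosen so every modality's group trend adds constructively
to the final contrast (a decrease in the signed term for a decrease in the
underlying parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .volumes import AnalysisMask, EmptyMaskError, MODALITIES, QuantitativeMap
from .inference import CohortStack

#: Valid metric tags: the three single parameters plus the joint estimator.
METRICS = MODALITIES + ("joint",)


@dataclass
class EstimatorSpec:
    """Metric choice plus the signs and CSF normalization factors.

    For single-parameter metrics the signs and normalization of the other
    modalities are ignored.
    """

    metric: str = "joint"
    signs: dict = field(default_factory=lambda: {m: 1 for m in MODALITIES})
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        for m, s in self.signs.items():
            if s not in (1, -1):
                raise ValueError(f"sign for {m} must be +1 or -1, got {s}")
        for m, n in self.normalization.items():
            if not n > 0:
                raise ValueError(f"normalization for {m} must be positive, got {n}")

    def to_config(self) -> dict:
        """YAML/JSON-friendly form: metric, signs.fw/t1/t2star, norm.fw/t1/t2star."""
        key = {"FW": "fw", "T1": "t1", "T2star": "t2star"}
        return {
            "metric": self.metric,
            "signs": {key[m]: s for m, s in self.signs.items()},
            "norm": {key[m]: n for m, n in self.normalization.items()},
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "EstimatorSpec":
        key = {"fw": "FW", "t1": "T1", "t2star": "T2star"}
        return cls(cfg.get("metric", "joint"),
                   {key[k]: v for k, v in cfg.get("signs", {}).items()} or
                   {m: 1 for m in MODALITIES},
                   {key[k]: v for k, v in cfg.get("norm", {}).items()})


@dataclass
class DifferenceMap:
    """Voxel-wise patient-mean minus control-mean of an estimator."""

    data: np.ndarray
    metric: str
    mask: AnalysisMask


def estimate_normalization(
    qmap: QuantitativeMap | np.ndarray,
    csf_mask: AnalysisMask,
    statistic: str = "median",
) -> float:
    """CSF reference value of one modality.

    The median over the CSF mask is the default — CSF masks at a high
    probability threshold still contain occasional partial-volume voxels,
    and the median ignores them; ``statistic="mean"`` is available.
    """
    if csf_mask.count == 0:
        raise EmptyMaskError("CSF mask is empty")
    data = qmap.data if isinstance(qmap, QuantitativeMap) else np.asarray(qmap)
    values = data[csf_mask.data]
    if statistic == "median":
        n = float(np.median(values))
    elif statistic == "mean":
        n = float(values.mean())
    else:
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    if not n > 0:
        raise ValueError(f"non-positive CSF normalization factor ({n}); check the CSF mask")
    return n


def compute_estimator(
    maps: Mapping[str, QuantitativeMap | np.ndarray],
    spec: EstimatorSpec,
) -> np.ndarray:
    """Evaluate the estimator voxel-wise.

    ``maps`` holds one map (or raw array) per modality.  Single metrics
    return the corresponding map unchanged; the joint metric returns the
    signed, CSF-normalized sum over all three modalities.
    """
    def _data(m):
        v = maps[m]
        return np.asarray(v.data if isinstance(v, QuantitativeMap) else v, dtype=np.float64)

    if spec.metric in MODALITIES:
        if spec.metric not in maps:
            raise KeyError(f"map for modality {spec.metric!r} missing")
        return _data(spec.metric)

    missing = [m for m in MODALITIES if m not in maps]
    if missing:
        raise KeyError(f"joint metric needs all modalities; missing {missing}")
    out = None
    for m in MODALITIES:
        n = spec.normalization.get(m)
        if n is None or not n > 0:
            raise ValueError(f"joint metric needs a positive normalization for {m}")
        term = spec.signs.get(m, 1) * _data(m) / n
        out = term if out is None else out + term
    return out


def suggest_signs(
    difference_maps: Mapping[str, DifferenceMap],
    roi: AnalysisMask,
) -> dict:
    """Choose per-modality signs from the single-metric group trends.

    The sign is +1 when the ROI median of the modality's difference map is
    non-positive (the parameter already trends downward in patients) and -1
    otherwise, so every signed term contributes a *decrease* to the joint
    metric and no modality degrades the contrast.  Ties default to +1.
    """
    if roi.count == 0:
        raise EmptyMaskError("sign suggestion over an empty ROI")
    signs = {}
    for m in MODALITIES:
        if m not in difference_maps:
            raise KeyError(f"difference map for modality {m!r} missing")
        med = float(np.median(difference_maps[m].data[roi.data]))
        signs[m] = 1 if med <= 0 else -1
    return signs


def difference_map(cohorts: CohortStack, mask: AnalysisMask | None = None) -> DifferenceMap:
    """d(E): voxel-wise patient mean minus control mean.

    Antisymmetric under cohort exchange; zero outside the mask.
    """
    if cohorts.n_controls == 0 or cohorts.n_patients == 0:
        raise ValueError("both cohorts must be nonempty")
    if mask is None:
        mask = cohorts.mask
    d = cohorts.patient.mean(axis=0, dtype=np.float64) - cohorts.control.mean(axis=0, dtype=np.float64)
    d = np.where(mask.data, d, 0.0)
    return DifferenceMap(d, cohorts.metric, mask)
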