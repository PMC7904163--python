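"""Voxel-wise group inference.

Each in-mask voxel carries two vectors of estimator values — one per
control subject, one per patient.  The analysis proceeds in three steps:

1. robust voxel elimination — any single value deviating from the voxel's
   reference mean by more than ``k`` reference standard deviations removes
   the voxel (both cohort vectors) from the analysis, which suppresses
   misregistration artifacts;
2. a one-tailed two-sample t-test per voxel against the null hypothesis
   "the metric has not decreased in patients";
3. thresholding the raw p-values into a binary H1 map.

No multiple-comparison correction is applied: false positives are handled
downstream by cluster size and solidity filtering, not by adjusting the
per-voxel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .volumes import AnalysisMask, EmptyMaskError, check_same_grid

#: Reference scopes for the k-SD elimination rule.
ELIMINATION_SCOPES = ("pooled", "per_group", "per_group_loo")


@dataclass
class CohortStack:
    """Per-voxel estimator vectors for the two cohorts.

    ``control`` and ``patient`` are 4D arrays of shape ``(n_subjects,) +
    grid``; statistics are only meaningful on ``mask``.
    """

    control: np.ndarray
    patient: np.ndarray
    mask: AnalysisMask
    metric: str = "joint"

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control)
        self.patient = np.asarray(self.patient)
        if self.control.ndim != 4 or self.patient.ndim != 4:
            raise ValueError("cohort stacks must be 4D: (n_subjects, x, y, z)")
        if self.control.shape[1:] != self.patient.shape[1:]:
            raise ValueError("control and patient grids differ")
        if self.control.shape[1:] != self.mask.shape:
            raise ValueError("cohort grid does not match mask grid")

    @property
    def n_controls(self) -> int:
        return self.control.shape[0]

    @property
    def n_patients(self) -> int:
        return self.patient.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.control.shape[1:]

    def swapped(self) -> "CohortStack":
        """The same data with the cohort labels exchanged."""
        return CohortStack(self.patient, self.control, self.mask, self.metric)


@dataclass
class PValueMap:
    """Raw one-sided p-values; 1.0 outside the mask."""

    data: np.ndarray
    mask: AnalysisMask
    alternative: str = "less"


@dataclass
class H1Map:
    """Binary map of voxels rejecting the null at level ``alpha``."""

    data: np.ndarray
    alpha: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def count(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# Voxel elimination
# ---------------------------------------------------------------------------

def _max_abs_standardized(values: np.ndarray) -> np.ndarray:
    """Per-voxel max |x - mean| / sd over axis 0, with 0/0 -> 0.

    ``values`` has shape (n, V).  Uses the sample SD (ddof=1).
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    dev = np.abs(values - mean).max(axis=0)
    out = np.full(values.shape[1], np.inf)
    zero_sd = sd == 0
    np.divide(dev, sd, out=out, where=~zero_sd)
    # constant vector: zero deviation from its own mean, never an outlier
    out[zero_sd & (dev == 0)] = 0.0
    return out


def eliminate_outlier_voxels(
    cohorts: CohortStack,
    k: float = 4.0,
    scope: str = "pooled",
) -> AnalysisMask:
    """Mask of voxels retained by the k-SD rule.

    A voxel is removed — both cohort vectors at once — when any of its
    values deviates from the reference mean by more than ``k`` reference
    SDs.  ``scope`` selects the reference population:

    - ``"pooled"`` (default): mean/SD of the concatenated 33-value vector.
      With the literal per-group inclusive statistics the standardized
      deviation of n values is bounded by (n-1)/sqrt(n) (about 3.61 at
      n=15), so a 4-SD rule can never fire within a small group; pooling
      the two cohorts removes that ceiling.
    - ``"per_group"``: the literal inclusive per-group reading, kept for
      comparison.
    - ``"per_group_loo"``: per group, each value standardized against the
      mean/SD of the *other* values of its group (leave-one-out).
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if scope not in ELIMINATION_SCOPES:
        raise ValueError(f"scope must be one of {ELIMINATION_SCOPES}, got {scope!r}")
    if cohorts.n_controls < 3 or cohorts.n_patients < 3:
        raise ValueError("elimination needs at least 3 subjects per cohort")

    m = cohorts.mask.data
    ctrl = cohorts.control[:, m].astype(np.float64)
    pat = cohorts.patient[:, m].astype(np.float64)

    if scope == "pooled":
        exceed = _max_abs_standardized(np.concatenate([ctrl, pat], axis=0)) > k
    elif scope == "per_group":
        exceed = (_max_abs_standardized(ctrl) > k) | (_max_abs_standardized(pat) > k)
    else:  # per_group_loo
        exceed = np.zeros(ctrl.shape[1], dtype=bool)
        for grp in (ctrl, pat):
            n = grp.shape[0]
            for i in range(n):
                rest = np.delete(grp, i, axis=0)
                mu = rest.mean(axis=0)
                sd = rest.std(axis=0, ddof=1)
                dev = np.abs(grp[i] - mu)
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.where(sd > 0, dev / sd, np.where(dev > 0, np.inf, 0.0))
                exceed |= z > k

    retained = np.zeros(cohorts.mask.shape, dtype=bool)
    retained[m] = ~exceed
    return AnalysisMask(retained, cohorts.mask.affine,
                        cohorts.mask.provenance + [f"{k}-SD elimination ({scope} scope)"])


# ---------------------------------------------------------------------------
# Voxel-wise test
# ---------------------------------------------------------------------------

def voxelwise_ttest(cohorts: CohortStack, variant: str = "pooled") -> PValueMap:
    """One-tailed two-sample t-test per voxel for a *decrease* in patients.

    The statistic is the classic two-means t with pooled variance
    (``variant="welch"`` switches to the unequal-variance form); the
    p-value is the lower-tail probability, so small p means the patient
    mean sits credibly below the control mean.  Degenerate voxels with zero
    pooled variance yield p = 1 for equal means (no evidence), and p = 0 or
    1 by the sign of the mean difference otherwise.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    n_c, n_p = cohorts.n_controls, cohorts.n_patients
    if n_c < 2 or n_p < 2:
        raise ValueError("each cohort needs at least 2 subjects")

    m = cohorts.mask.data
    ctrl = cohorts.control[:, m].astype(np.float64)
    pat = cohorts.patient[:, m].astype(np.float64)

    mean_c = ctrl.mean(axis=0)
    mean_p = pat.mean(axis=0)
    var_c = ctrl.var(axis=0, ddof=1)
    var_p = pat.var(axis=0, ddof=1)
    diff = mean_p - mean_c

    if variant == "pooled":
        df = np.full(diff.shape, float(n_c + n_p - 2))
        pooled = ((n_c - 1) * var_c + (n_p - 1) * var_p) / (n_c + n_p - 2)
        se = np.sqrt(pooled * (1.0 / n_c + 1.0 / n_p))
    else:
        a, b = var_c / n_c, var_p / n_p
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a ** 2 / (n_c - 1) + b ** 2 / (n_p - 1))
        df = np.where(np.isfinite(df), df, 1.0)

    p = np.ones(diff.shape)
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff[ok] / se[ok]
    p[ok] = special.stdtr(df[ok], t)
    # zero-variance voxels: decide by the sign of the difference alone
    p[~ok & (diff < 0)] = 0.0
    p[~ok & (diff >= 0)] = 1.0

    out = np.ones(cohorts.mask.shape)
    out[m] = p
    return PValueMap(out, cohorts.mask, alternative="less")


def h1_map(p: PValueMap, alpha: float = 0.05) -> H1Map:
    """Binary rejection map: true exactly where p < alpha (strict)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return H1Map((p.data < alpha) & p.mask.data, alpha, p.mask.affine)


def rejection_fraction(h1: H1Map, region: AnalysisMask) -> float:
    """Fraction of region voxels rejecting the null."""
    n_region = region.count
    if n_region == 0:
        raise EmptyMaskError("rejection fraction over an empty region")
    return float((h1.data & region.data).sum()) / n_region


# ---------------------------------------------------------------------------
# Difference histograms
# ---------------------------------------------------------------------------

@dataclass
class DifferenceHistogram:
    """Density-normalized histogram of d(E) over a region.

    Densities integrate to the in-range mass; the cropped tails are
    reported separately so outliers remain accounted for.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    frac_below: float
    frac_above: float
    n_values: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "density": self.density,
        })


def difference_histogram(
    d,
    region: AnalysisMask,
    bins: int = 100,
    crop: tuple[float, float] | None = None,
) -> DifferenceHistogram:
    """Histogram of per-voxel group differences over ``region``.

    With no explicit ``crop`` range, bins span the central 99% of the
    values (0.5th to 99.5th percentile) so a handful of extreme
    misregistration voxels cannot flatten the display; the mass outside
    the range is reported in ``frac_below`` / ``frac_above``.
    """
    if region.count == 0:
        raise EmptyMaskError("histogram over an empty region")
    data = np.asarray(d.data if hasattr(d, "data") else d)
    values = data[region.data].astype(np.float64)
    if crop is None:
        lo, hi = np.percentile(values, [0.5, 99.5])
        if lo == hi:  # constant input: widen to a unit-width window
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = crop
        if lo >= hi:
            raise ValueError("crop range must be increasing")
    in_range = (values >= lo) & (values <= hi)
    frac_below = float((values < lo).mean())
    frac_above = float((values > hi).mean())
    counts, edges = np.histogram(values[in_range], bins=bins, range=(lo, hi))
    widths = np.diff(edges)
    total = values.size
    density = counts / (total * widths)
    return DifferenceHistogram(edges, density, frac_below, frac_above, total)
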