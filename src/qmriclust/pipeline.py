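"""End-to-end orchestration of the group analysis.

The in-memory core is :func:`analyze_cohorts`; :func:`run_pipeline` wraps
it with NIfTI/TSV/JSON file handling for the CLI, and
:func:`run_phantom_study` closes the loop on synthetic data by scoring
detected clusters against the phantom's ground truth.

Stage order per metric: tissue masking -> CSF normalization -> estimator
computation (with sign suggestion for the joint metric) -> k-SD voxel
elimination -> one-tailed t-test -> H1 map -> 18-connected labeling ->
size and solidity filtering -> ranking -> reports and histograms.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import inference as inf
from . import metrics as me
from . import phantom as ph
from . import volumes as vol
from .volumes import AnalysisMask, EmptyMaskError, GridMismatchError

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class AnalysisParams:
    """All statistical knobs of the pipeline, with the method's defaults."""

    metrics: tuple = me.METRICS
    tissue_threshold: float = 0.95
    alpha: float = 0.05
    elimination_k: float = 4.0
    elimination_scope: str = "pooled"
    min_cluster_size: int = 27
    min_solidity: float = 0.1
    ttest_variant: str = "pooled"
    norm_statistic: str = "median"
    histogram_bins: int = 100
    #: "auto": suggest joint-metric signs from single-metric trends when a
    #: search ROI is given, otherwise keep +1 — aligning signs on the whole
    #: mask with no hypothesis region would be circular; "suggest"/"fixed"
    #: force either behavior.
    sign_mode: str = "auto"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 <= self.tissue_threshold <= 1.0):
            raise ConfigError(f"tissue threshold must lie in [0, 1], got {self.tissue_threshold}")
        if self.elimination_k <= 0:
            raise ConfigError(f"elimination k must be positive, got {self.elimination_k}")
        if self.min_cluster_size < 1:
            raise ConfigError("min cluster size must be >= 1")
        if not (0.0 <= self.min_solidity <= 1.0):
            raise ConfigError("min solidity must lie in [0, 1]")
        if self.elimination_scope not in inf.ELIMINATION_SCOPES:
            raise ConfigError(f"unknown elimination scope {self.elimination_scope!r}")
        unknown = [m for m in self.metrics if m not in me.METRICS]
        if unknown:
            raise ConfigError(f"unknown metrics {unknown}")
        if self.sign_mode not in ("auto", "suggest", "fixed"):
            raise ConfigError(f"unknown sign mode {self.sign_mode!r}")


@dataclass
class MetricResult:
    """Everything the pipeline produced for one metric."""

    metric: str
    spec: me.EstimatorSpec
    analysis_mask: AnalysisMask
    p: inf.PValueMap
    h1: inf.H1Map
    clusters_raw: cl.ClusterSet
    clusters: cl.ClusterSet
    diff: me.DifferenceMap
    histogram: inf.DifferenceHistogram
    histogram_roi: inf.DifferenceHistogram | None
    report: pd.DataFrame
    n_voxels_in: int
    n_voxels_retained: int


@dataclass
class StudyResult:
    metrics: dict
    normalization: dict
    signs: dict
    brain_mask: AnalysisMask
    roi: AnalysisMask | None
    summary: dict


def _largest_in_roi(ranked: cl.ClusterSet, roi: AnalysisMask | None) -> bool | None:
    """True when the two biggest surviving clusters sit mostly inside the ROI."""
    if roi is None:
        return None
    top = [c for c in ranked.clusters if c.rank is not None and c.rank <= 2]
    if not top:
        return False
    return all(roi.data[tuple(c.voxels.T)].mean() > 0.5 for c in top)


def analyze_cohorts(
    maps: dict,
    wm_probability: np.ndarray,
    gm_probability: np.ndarray,
    csf_probability: np.ndarray,
    roi: AnalysisMask | None = None,
    atlas: np.ndarray | None = None,
    atlas_labels: dict | None = None,
    params: AnalysisParams | None = None,
    affine: np.ndarray | None = None,
) -> StudyResult:
    """Run the full voxel-wise analysis on in-memory cohort stacks.

    ``maps`` maps each modality to a pair ``(controls, patients)`` of 4D
    arrays ``(n_subjects, x, y, z)`` of co-registered quantitative values.
    """
    params = params or AnalysisParams()
    params.validate()
    if affine is None:
        affine = np.eye(4)

    for mod in vol.MODALITIES:
        if mod not in maps:
            raise ConfigError(f"maps for modality {mod!r} missing")

    wm = vol.tissue_mask(wm_probability, params.tissue_threshold, affine)
    gm = vol.tissue_mask(gm_probability, params.tissue_threshold, affine)
    csf = vol.tissue_mask(csf_probability, params.tissue_threshold, affine)
    brain = wm.union(gm)
    if brain.count == 0:
        raise EmptyMaskError("analysis mask (WM | GM) is empty")
    if roi is not None:
        vol.check_same_grid(brain, roi)

    t0 = time.perf_counter()
    # global CSF normalization factors from the control cohort's mean maps
    normalization = {
        mod: me.estimate_normalization(maps[mod][0].mean(axis=0, dtype=np.float64),
                                       csf, params.norm_statistic)
        for mod in vol.MODALITIES
    }

    # single-metric trends decide the joint metric's signs (within the ROI)
    suggest = params.sign_mode == "suggest" or (params.sign_mode == "auto"
                                                and roi is not None)
    if suggest:
        single_diffs = {}
        for mod in vol.MODALITIES:
            stack = inf.CohortStack(maps[mod][0], maps[mod][1], brain, mod)
            single_diffs[mod] = me.difference_map(stack)
        signs = me.suggest_signs(single_diffs, roi if roi is not None else brain)
    else:
        signs = {m: 1 for m in vol.MODALITIES}
    logger.info("normalization=%s signs=%s (%.1fs)", normalization, signs,
                time.perf_counter() - t0)

    results: dict[str, MetricResult] = {}
    summary_metrics = {}
    for metric in params.metrics:
        t0 = time.perf_counter()
        spec = me.EstimatorSpec(metric, dict(signs), dict(normalization))
        if metric == "joint":
            n_c = maps[vol.MODALITIES[0]][0].shape[0]
            n_p = maps[vol.MODALITIES[0]][1].shape[0]
            ctrl = np.zeros((n_c,) + brain.shape, dtype=np.float64)
            pat = np.zeros((n_p,) + brain.shape, dtype=np.float64)
            for mod in vol.MODALITIES:
                ctrl += signs[mod] * maps[mod][0].astype(np.float64) / normalization[mod]
                pat += signs[mod] * maps[mod][1].astype(np.float64) / normalization[mod]
        else:
            ctrl, pat = maps[metric]

        stack = inf.CohortStack(ctrl, pat, brain, metric)
        retained = inf.eliminate_outlier_voxels(stack, params.elimination_k,
                                                params.elimination_scope)
        final_mask = vol.combine_masks(wm, gm, retained)
        stack = inf.CohortStack(ctrl, pat, final_mask, metric)

        p = inf.voxelwise_ttest(stack, params.ttest_variant)
        h1 = inf.h1_map(p, params.alpha)
        raw = cl.label_clusters(h1)
        filtered = cl.solidity_filter(cl.size_filter(raw, params.min_cluster_size),
                                      params.min_solidity)
        ranked = cl.rank_clusters(filtered)
        diff = me.difference_map(stack)
        hist = inf.difference_histogram(diff, final_mask, params.histogram_bins)
        hist_roi = (inf.difference_histogram(diff, roi, params.histogram_bins)
                    if roi is not None and roi.count else None)
        report = cl.cluster_report(ranked, roi=roi, atlas=atlas, atlas_labels=atlas_labels)

        results[metric] = MetricResult(
            metric, spec, final_mask, p, h1, raw, ranked, diff, hist, hist_roi,
            report, brain.count, final_mask.count,
        )
        top = ranked.clusters[0] if ranked.clusters else None
        summary_metrics[metric] = {
            "voxels_in_mask": brain.count,
            "voxels_retained": final_mask.count,
            "voxels_eliminated": brain.count - final_mask.count,
            "n_h1_voxels": h1.count,
            "n_clusters": len(raw),
            "n_clusters_after_elimination": len(ranked),
            "largest_cluster_voxels": top.size if top else 0,
            "largest_cluster_solidity": round(top.solidity, 4) if top else None,
            "largest_clusters_in_roi": _largest_in_roi(ranked, roi),
        }
        logger.info("metric %s: %d -> %d clusters (%.1fs)", metric, len(raw),
                    len(ranked), time.perf_counter() - t0)

    summary = {
        "n_controls": maps[vol.MODALITIES[0]][0].shape[0],
        "n_patients": maps[vol.MODALITIES[0]][1].shape[0],
        "normalization": {k: round(v, 6) for k, v in normalization.items()},
        "signs": signs,
        "params": asdict(params) | {"metrics": list(params.metrics)},
        "metrics": summary_metrics,
    }
    return StudyResult(results, normalization, signs, brain, roi, summary)


# ---------------------------------------------------------------------------
# File-based runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File-level description of one study run (YAML-serializable)."""

    controls: list = field(default_factory=list)   # [{modality: path}, ...]
    patients: list = field(default_factory=list)
    wm_probability: str = ""
    gm_probability: str = ""
    csf_probability: str = ""
    roi: str | None = None
    atlas: str | None = None
    atlas_labels: str | None = None
    output_dir: str = "qmriclust_out"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        params = AnalysisParams(**raw.pop("params", {}))
        subjects = raw.pop("subjects", {})
        try:
            cfg = cls(controls=subjects.get("controls", []),
                      patients=subjects.get("patients", []),
                      params=params, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        return cfg

    def validate(self) -> None:
        self.params.validate()
        if len(self.controls) < 2 or len(self.patients) < 2:
            raise ConfigError("each cohort needs at least 2 subjects")
        for group in (self.controls, self.patients):
            for entry in group:
                missing = [m for m in vol.MODALITIES if m not in entry]
                if missing:
                    raise ConfigError(f"subject entry {entry} lacks modalities {missing}")
        for p in (self.wm_probability, self.gm_probability, self.csf_probability):
            if not p or not Path(p).exists():
                raise ConfigError(f"tissue probability map not found: {p!r}")
        for p in (self.roi, self.atlas):
            if p and not Path(p).exists():
                raise ConfigError(f"mask not found: {p}")


def _load_probability(path: str) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(path)
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def run_pipeline(config: PipelineConfig) -> StudyResult:
    """Load inputs, run :func:`analyze_cohorts`, write the result bundle."""
    config.validate()
    wm_prob, affine = _load_probability(config.wm_probability)
    gm_prob, _ = _load_probability(config.gm_probability)
    csf_prob, _ = _load_probability(config.csf_probability)

    maps = {}
    for mod in vol.MODALITIES:
        ctrl = np.stack([vol.load_map(s[mod], mod).data for s in config.controls])
        pat = np.stack([vol.load_map(s[mod], mod).data for s in config.patients])
        if ctrl.shape[1:] != wm_prob.shape or pat.shape[1:] != wm_prob.shape:
            raise GridMismatchError(f"{mod} maps do not match the tissue grid")
        maps[mod] = (ctrl, pat)

    roi = vol.load_mask(config.roi) if config.roi else None
    atlas = atlas_labels = None
    if config.atlas:
        atlas = np.asarray(np.rint(_load_probability(config.atlas)[0]), dtype=np.int32)
        if config.atlas_labels:
            atlas_labels = {int(k): v for k, v in
                            json.loads(Path(config.atlas_labels).read_text()).items()}

    result = analyze_cohorts(maps, wm_prob, gm_prob, csf_prob, roi=roi, atlas=atlas,
                             atlas_labels=atlas_labels, params=config.params,
                             affine=affine)
    write_study_result(result, config.output_dir, affine)
    return result


def write_study_result(result: StudyResult, out_dir: str | Path,
                       affine: np.ndarray | None = None) -> None:
    """Write NIfTI intermediates, TSV tables, JSON summary and provenance."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = result.brain_mask.affine

    def _save(data, name, dtype):
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(out / name))

    _save(result.brain_mask.data.astype(np.uint8), "analysis_mask.nii.gz", np.uint8)
    if result.roi is not None:
        _save(result.roi.data.astype(np.uint8), "roi.nii.gz", np.uint8)

    for metric, res in result.metrics.items():
        _save(res.p.data, f"{metric}_pvalues.nii.gz", np.float32)
        _save(res.h1.data.astype(np.uint8), f"{metric}_h1.nii.gz", np.uint8)
        _save(res.clusters.labels_volume(), f"{metric}_clusters.nii.gz", np.int32)
        _save(res.diff.data, f"{metric}_difference.nii.gz", np.float32)
        res.report.to_csv(out / f"{metric}_clusters.tsv", sep="\t", index=False)
        res.histogram.to_frame().to_csv(out / f"{metric}_histogram.tsv", sep="\t", index=False)
        if res.histogram_roi is not None:
            res.histogram_roi.to_frame().to_csv(out / f"{metric}_histogram_roi.tsv",
                                                sep="\t", index=False)
        _plot_histogram(res, out / f"{metric}_histogram.png")

    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    (out / "provenance.yaml").write_text(yaml.safe_dump({
        "params": result.summary["params"],
        "normalization": result.summary["normalization"],
        "signs": result.signs,
        "mask_provenance": result.brain_mask.provenance,
    }, sort_keys=False))


def _plot_histogram(res: MetricResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    h = res.histogram
    ax.stairs(h.density, h.bin_edges, fill=True, alpha=0.5, label="all voxels")
    if res.histogram_roi is not None:
        hr = res.histogram_roi
        ax.stairs(hr.density, hr.bin_edges, fill=True, alpha=0.5, label="ROI")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(f"d(E), {res.metric}")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Phantom study
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def score_against_truth(res: MetricResult, truth: ph.PhantomTruth,
                        shape: tuple[int, ...]) -> dict:
    """Compare a metric's surviving ranked clusters with injected truth."""
    truth_union = np.zeros(shape, dtype=bool)
    for m in truth.effect_masks:
        truth_union |= m
    top2 = np.zeros(shape, dtype=bool)
    for c in res.clusters.clusters:
        if c.rank is not None and c.rank <= 2:
            top2[tuple(c.voxels.T)] = True
    per_truth = []
    for m in truth.effect_masks:
        best_dice, best_rank = 0.0, None
        for c in res.clusters.clusters:
            d = dice(c.to_mask(shape), m)
            if d > best_dice:
                best_dice, best_rank = d, c.rank
        per_truth.append({"dice": best_dice, "rank": best_rank})
    false_pos = sum(1 for c in res.clusters.clusters
                    if not truth_union[tuple(c.voxels.T)].any())
    largest = max((c.size for c in res.clusters.clusters), default=0)
    return {
        "metric": res.metric,
        "dice_top2": dice(top2, truth_union) if truth.effect_masks else None,
        "true_cluster_matches": per_truth,
        "n_surviving_clusters": len(res.clusters),
        "n_false_positive_clusters": false_pos,
        "largest_cluster_voxels": largest,
    }


def run_phantom_study(
    spec: ph.PhantomSpec,
    params: AnalysisParams | None = None,
    roi_target_voxels: int = 1000,
) -> tuple[StudyResult, pd.DataFrame]:
    """Generate a phantom, analyze it, and score detections against truth.

    When effects are injected, the search ROI is built the way a rough
    anatomical contour would be: the union of the true effect regions
    dilated to about ``roi_target_voxels`` voxels.
    """
    data = ph.generate_cohorts(spec)
    roi = None
    if data.truth.effect_masks:
        seed_mask = np.zeros(spec.shape, dtype=bool)
        for m in data.truth.effect_masks:
            seed_mask |= m
        roi = vol.dilate_to_size(AnalysisMask(seed_mask, data.affine, ["truth seed"]),
                                 max(roi_target_voxels, int(seed_mask.sum())))
    result = analyze_cohorts(
        data.maps,
        data.tissue_probability["WM"],
        data.tissue_probability["GM"],
        data.tissue_probability["CSF"],
        roi=roi, params=params, affine=data.affine,
    )
    rows = [score_against_truth(res, data.truth, spec.shape)
            for res in result.metrics.values()]
    return result, pd.DataFrame(rows)
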