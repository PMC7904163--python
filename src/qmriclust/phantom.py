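"""Synthetic co-registered two-cohort phantom with known ground truth.

The phantom emulates the structure of a co-registered group study of
quantitative maps without any real anatomy: three nested ellipsoids stand
in for a WM core, a GM ribbon and a CSF shell on an MNI-like 2 mm grid.
Each subject's map of a modality is

    compartment mean + subject offset + voxel noise

where the subject offset is one scalar per subject, compartment and
modality drawn from the between-subject SD (the spread reported for real
control cohorts), and the voxel noise is an independent Gaussian field
whose SD defaults to 1% of the compartment mean.  Patients additionally
carry fractional decreases of all three parameters inside injected
ellipsoidal effect clusters, the synthetic stand-in for a bilateral
pathological structure such as the substantia nigra.  Sporadic outlier
voxels emulate the residue of imperfect registration.

Everything is driven by one seed through ``numpy.random.SeedSequence``
spawning (one child stream per cohort plus one for outliers), so each
stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import MODALITIES, AnalysisMask

#: Compartment statistics: (mean, between-subject SD) per modality for
#: healthy controls.  GM/WM values follow published whole-brain control
#: cohort statistics; CSF is the normalization reference (FW is 100% of
#: CSF by definition; T1/T2* are long in free fluid).
DEFAULT_COMPARTMENT_STATS = {
    "GM": {"FW": (83.0, 1.0), "T1": (1501.0, 40.0), "T2star": (56.0, 5.0)},
    "WM": {"FW": (73.0, 2.0), "T1": (1169.0, 85.0), "T2star": (48.0, 5.0)},
    "CSF": {"FW": (100.0, 0.5), "T1": (4000.0, 100.0), "T2star": (1500.0, 100.0)},
}

#: Integer labels of the nested-ellipsoid layout.
LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3}

#: Outer semi-axis of each compartment as a fraction of the half grid size.
_COMPARTMENT_EXTENT = {"CSF": 0.92, "GM": 0.80, "WM": 0.55}


@dataclass
class EffectCluster:
    """One injected ellipsoidal effect region.

    ``decrease`` maps modality -> fractional reduction applied to patients
    (0.05 = a 5% drop).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    decrease: dict

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        return ellipsoid_mask(shape, self.center, self.semi_axes)


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic study."""

    shape: tuple[int, int, int] = (91, 109, 91)
    compartment_stats: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_COMPARTMENT_STATS.items()})
    within_noise_frac: float = 0.01
    effects: list = field(default_factory=list)
    outlier_probability: float = 0.0
    outlier_magnitude_sd: float = 6.0
    n_controls: int = 15
    n_patients: int = 18
    seed: int = 0
    labels: np.ndarray | None = None  # user-supplied label volume overrides ellipsoids

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("each cohort needs at least 2 subjects")
        for comp, stats in self.compartment_stats.items():
            for m, (mean, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {comp}/{m}")


@dataclass
class PhantomTruth:
    """Ground truth of one generated study."""

    effect_masks: list          # one bool volume per injected cluster
    effects: list               # the EffectCluster specs
    outliers: list              # (cohort, subject_index, flat voxel indices)
    labels: np.ndarray          # compartment label volume


@dataclass
class PhantomData:
    """Generated cohorts plus tissue maps and truth."""

    maps: dict                  # modality -> (controls (n_c,*shape), patients (n_p,*shape))
    tissue_probability: dict    # 'WM'/'GM'/'CSF' -> float volume in {0,1}
    truth: PhantomTruth
    spec: PhantomSpec
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    """Voxels whose centers lie inside the ellipsoid (boundary inclusive)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def nested_ellipsoid_labels(shape=(91, 109, 91)) -> np.ndarray:
    """Crude brain layout: CSF shell around a GM ribbon around a WM core."""
    center = [(s - 1) / 2.0 for s in shape]
    half = [s / 2.0 for s in shape]
    labels = np.zeros(shape, dtype=np.int8)
    for comp in ("CSF", "GM", "WM"):  # paint outside-in; inner overwrites outer
        axes = [_COMPARTMENT_EXTENT[comp] * h for h in half]
        labels[ellipsoid_mask(shape, center, axes)] = LABELS[comp]
    return labels


def default_effect_decreases(
    compartment: str = "GM",
    sd_multiple: float = 2.0,
    stats: dict | None = None,
) -> dict:
    """Fractional decreases equal to ``sd_multiple`` between-subject SDs of
    the host compartment, per modality."""
    stats = stats or DEFAULT_COMPARTMENT_STATS
    return {m: sd_multiple * stats[compartment][m][1] / stats[compartment][m][0]
            for m in MODALITIES}


def bilateral_sn_layout(
    shape=(91, 109, 91),
    size_voxels: int = 700,
    decrease: dict | None = None,
) -> list:
    """Two mirror-symmetric spherical effect clusters in deep tissue.

    The pair sits left/right of the midline, emulating the bilateral
    geometry of a deep midbrain nucleus; each sphere's radius is chosen so
    the discrete voxel count is close to ``size_voxels``.
    """
    if decrease is None:
        decrease = default_effect_decreases()
    mid = (shape[0] - 1) / 2.0
    offset = 0.62 * shape[0] / 2.0
    cy, cz = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    center = (mid - offset, cy, cz)
    # smallest radius whose discrete sphere at this center reaches the target
    radius = max((3.0 * size_voxels / (4.0 * np.pi)) ** (1.0 / 3.0) - 1.0, 0.5)
    while ellipsoid_mask(shape, center, (radius,) * 3).sum() < size_voxels:
        radius += 0.1
        if radius > min(shape) / 2.0:
            raise ValueError(f"cannot fit a {size_voxels}-voxel cluster in grid {shape}")
    return [
        EffectCluster(center, (radius,) * 3, dict(decrease)),
        EffectCluster((mid + offset, cy, cz), (radius,) * 3, dict(decrease)),
    ]


def _subject_map(rng, template, sd_by_comp, labels, within_sd) -> np.ndarray:
    out = template.copy()
    for comp, sd in sd_by_comp.items():
        if sd > 0:
            out[labels == LABELS[comp]] += rng.normal(0.0, sd)
    noise = rng.standard_normal(template.shape, dtype=np.float32)
    out += noise * within_sd
    out[labels == 0] = 0.0
    return out


def generate_cohorts(spec: PhantomSpec) -> PhantomData:
    """Draw both cohorts for all modalities; deterministic under the seed."""
    labels = spec.labels if spec.labels is not None else nested_ellipsoid_labels(spec.shape)
    labels = np.asarray(labels)
    if labels.shape != tuple(spec.shape):
        raise ValueError("label volume shape does not match spec.shape")
    tissue = labels > 0

    effect_masks = []
    for eff in spec.effects:
        m = eff.mask(labels.shape)
        if (m & ~((labels == LABELS["GM"]) | (labels == LABELS["WM"]))).any():
            raise ValueError("effect cluster extends outside GM and WM")
        effect_masks.append(m)

    templates, within_sds = {}, {}
    for mod in MODALITIES:
        t = np.zeros(labels.shape, dtype=np.float32)
        for comp in ("CSF", "GM", "WM"):
            mean, _ = spec.compartment_stats[comp][mod]
            t[labels == LABELS[comp]] = mean
        templates[mod] = t
        within_sds[mod] = spec.within_noise_frac * t

    root = np.random.SeedSequence(spec.seed)
    ss_ctrl, ss_pat, ss_out = root.spawn(3)
    rng_ctrl = np.random.default_rng(ss_ctrl)
    rng_pat = np.random.default_rng(ss_pat)

    maps = {}
    for mod in MODALITIES:
        sd_by_comp = {c: spec.compartment_stats[c][mod][1] for c in ("CSF", "GM", "WM")}
        ctrl = np.stack([
            _subject_map(rng_ctrl, templates[mod], sd_by_comp, labels, within_sds[mod])
            for _ in range(spec.n_controls)])
        pats = []
        for _ in range(spec.n_patients):
            m = _subject_map(rng_pat, templates[mod], sd_by_comp, labels, within_sds[mod])
            for eff, emask in zip(spec.effects, effect_masks):
                m[emask] *= 1.0 - eff.decrease.get(mod, 0.0)
            pats.append(m)
        maps[mod] = (ctrl, np.stack(pats))

    tissue_probability = {
        comp: (labels == LABELS[comp]).astype(np.float32)
        for comp in ("WM", "GM", "CSF")
    }
    truth = PhantomTruth(effect_masks, list(spec.effects), [], labels)
    data = PhantomData(maps, tissue_probability, truth, spec)

    if spec.outlier_probability > 0:
        inject_outliers(data, spec.outlier_probability, spec.outlier_magnitude_sd,
                        rng=np.random.default_rng(ss_out))
    return data


def inject_outliers(
    data: PhantomData,
    probability: float,
    magnitude_sd: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list:
    """Shift sporadic voxels of individual subjects by ±magnitude_sd
    between-subject SDs of their compartment, emulating misregistration.

    Outlier voxel positions are drawn per subject and shared across
    modalities (a registration error displaces all maps of that subject
    identically); signs are drawn per modality.  Modifies ``data`` in
    place and returns the outlier record ``(cohort, subject, flat voxel
    indices)``, which is also appended to ``data.truth.outliers``.
    """
    if not (0.0 <= probability <= 1.0):
        raise ValueError("outlier probability must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = data.truth.labels
    tissue_idx = np.flatnonzero(labels > 0)
    lab_flat = labels.reshape(-1)
    records = []
    for cohort_name, cohort_pos in (("control", 0), ("patient", 1)):
        n_subj = data.maps[MODALITIES[0]][cohort_pos].shape[0]
        for s in range(n_subj):
            hit = tissue_idx[rng.random(tissue_idx.size) < probability]
            if hit.size == 0:
                continue
            for mod in MODALITIES:
                vol = data.maps[mod][cohort_pos][s].reshape(-1)
                signs = rng.choice([-1.0, 1.0], size=hit.size)
                for comp in ("CSF", "GM", "WM"):
                    sd = data.spec.compartment_stats[comp][mod][1]
                    sel = hit[lab_flat[hit] == LABELS[comp]]
                    if sel.size:
                        vol[sel] += signs[lab_flat[hit] == LABELS[comp]] * magnitude_sd * sd
            records.append((cohort_name, s, hit))
    data.truth.outliers.extend(records)
    return records


def brain_mask(data: PhantomData) -> AnalysisMask:
    """GM-or-WM mask of the phantom (the analysis search space)."""
    labels = data.truth.labels
    return AnalysisMask((labels == LABELS["GM"]) | (labels == LABELS["WM"]),
                        data.affine, ["phantom GM|WM"])
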