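"""Volume and mask handling for co-registered quantitative MRI maps.

All maps and masks entering one analysis must share a grid (shape plus
affine); the package works in voxel index space and never resamples —
inputs are co-registered by contract.  Affines are carried through to
output files unchanged.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Recognised quantitative modalities and their physical units.
MODALITIES = ("T1", "T2star", "FW")
UNITS = {"T1": "ms", "T2star": "ms", "FW": "percent-of-CSF"}


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class EmptyMaskError(ValueError):
    """A mask required to be nonempty is empty."""


def _check_modality(modality: str) -> str:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return modality


@dataclass
class QuantitativeMap:
    """One subject's 3D scalar map for one modality.

    Parameters
    ----------
    data:
        3D array of parameter values (T1/T2* in ms, FW in percent of CSF).
    modality:
        One of ``"T1"``, ``"T2star"``, ``"FW"``.
    affine:
        4x4 voxel-to-world affine, carried through for output only.
    """

    data: np.ndarray
    modality: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        _check_modality(self.modality)
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def units(self) -> str:
        return UNITS[self.modality]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in world units (mm for standard NIfTI)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class AnalysisMask:
    """Binary voxel mask with a record of how it was built."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def union(self, other: "AnalysisMask") -> "AnalysisMask":
        check_same_grid(self, other)
        return AnalysisMask(self.data | other.data, self.affine,
                            self.provenance + other.provenance + ["union"])

    def intersection(self, other: "AnalysisMask") -> "AnalysisMask":
        check_same_grid(self, other)
        return AnalysisMask(self.data & other.data, self.affine,
                            self.provenance + other.provenance + ["intersection"])


def check_same_grid(*volumes) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share shape and affine."""
    if not volumes:
        return
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape:
            raise GridMismatchError(f"shape mismatch: {v.shape} vs {ref.shape}")
        if not np.allclose(v.affine, ref.affine, atol=1e-4):
            raise GridMismatchError("affine mismatch between volumes")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_map(
    path: str | Path,
    modality: str,
    volume_index: int | None = None,
    brain_mask: AnalysisMask | None = None,
) -> QuantitativeMap:
    """Read a 3D quantitative map from a NIfTI file.

    A 4D file is rejected unless ``volume_index`` selects one volume.  If a
    brain mask is supplied, non-finite voxels inside it are replaced by zero
    and removed from the mask *in place*, with a warning — this mirrors how
    failed per-voxel fits are handled upstream of group analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if volume_index is None:
            raise ValueError(f"{path} is 4D; pass volume_index to select one volume")
        data = data[..., volume_index]
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D volume")
    data = np.asarray(data, dtype=np.float64)

    if brain_mask is not None:
        check_same_grid(brain_mask, QuantitativeMap(data, modality, img.affine))
        bad = ~np.isfinite(data) & brain_mask.data
        n_bad = int(bad.sum())
        if n_bad:
            warnings.warn(
                f"{path.name}: {n_bad} non-finite voxel(s) inside brain mask; "
                "set to 0 and removed from mask",
                stacklevel=2,
            )
            data[bad] = 0.0
            brain_mask.data &= ~bad
            brain_mask.provenance.append(f"removed {n_bad} non-finite voxels ({path.name})")
    data[~np.isfinite(data)] = 0.0
    return QuantitativeMap(data, modality, img.affine)


def save_map(qmap: QuantitativeMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(qmap.data, dtype=np.float32), qmap.affine), str(path))


def save_mask(mask: AnalysisMask, path: str | Path) -> None:
    """Write a mask as uint8 {0,1} NIfTI plus a JSON provenance sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = sidecar.parent / (sidecar.name + ".json")
    sidecar.write_text(json.dumps({"provenance": mask.provenance}, indent=2))


def load_mask(path: str | Path) -> AnalysisMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D mask")
    return AnalysisMask(data > 0, img.affine, [f"loaded from {path.name}"])


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------

def tissue_mask(
    probability_map: np.ndarray | QuantitativeMap,
    threshold: float = 0.95,
    affine: np.ndarray | None = None,
) -> AnalysisMask:
    """Threshold a tissue probability map.

    The comparison is strict (``probability > threshold``): a voxel exactly
    at the threshold is excluded, which suppresses partial-volume voxels at
    compartment interfaces.
    """
    if isinstance(probability_map, QuantitativeMap):
        if affine is None:
            affine = probability_map.affine
        probability_map = probability_map.data
    probability_map = np.asarray(probability_map)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if probability_map.min() < 0 or probability_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    if affine is None:
        affine = np.eye(4)
    return AnalysisMask(probability_map > threshold, affine,
                        [f"tissue probability > {threshold}"])


def combine_masks(wm: AnalysisMask, gm: AnalysisMask, elimination: AnalysisMask) -> AnalysisMask:
    """Final analysis mask: ``(WM | GM) & elimination``.

    WM and GM are disjoint at a high probability threshold, so their tissue
    contribution enters as a union; the elimination mask (voxels retained by
    the outlier rule) then restricts it.
    """
    check_same_grid(wm, gm, elimination)
    out = (wm.data | gm.data) & elimination.data
    prov = ["(WM | GM) & elimination",
            *[f"wm: {p}" for p in wm.provenance],
            *[f"gm: {p}" for p in gm.provenance],
            *[f"elim: {p}" for p in elimination.provenance]]
    return AnalysisMask(out, wm.affine, prov)


def spherical_element(radius: float) -> np.ndarray:
    """Discrete ball: offsets with Euclidean distance <= radius from the center."""
    r = int(np.floor(radius))
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 + zz ** 2) <= radius ** 2 + 1e-12


def dilate_to_size(seed: AnalysisMask, target_voxels: int, max_radius: int = 64) -> AnalysisMask:
    """Dilate a seed mask with discrete balls of growing radius until it
    contains at least ``target_voxels`` voxels.

    The first radius reaching the target wins; the result always contains
    the seed.  A target at or below the seed size returns the seed unchanged
    (with a warning when strictly below).
    """
    if seed.count == 0:
        raise EmptyMaskError("cannot dilate an empty seed mask")
    if target_voxels < seed.count:
        warnings.warn(
            f"target ({target_voxels}) below seed size ({seed.count}); returning seed unchanged",
            stacklevel=2,
        )
        return AnalysisMask(seed.data.copy(), seed.affine,
                            seed.provenance + ["dilation skipped: already at target"])
    if target_voxels == seed.count:
        return AnalysisMask(seed.data.copy(), seed.affine,
                            seed.provenance + ["dilation skipped: already at target"])
    for radius in range(1, max_radius + 1):
        dilated = ndimage.binary_dilation(seed.data, structure=spherical_element(radius))
        if int(dilated.sum()) >= target_voxels:
            return AnalysisMask(dilated, seed.affine,
                                seed.provenance + [f"dilated with ball radius {radius} "
                                                   f"to {int(dilated.sum())} voxels"])
    raise RuntimeError(f"target of {target_voxels} voxels not reached within radius {max_radius}")
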