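import nibabel as nib
import numpy as np
import pytest

from qmriclust import AnalysisMask


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def write_nifti(tmp_path):
    """Write an array to a temporary NIfTI file and return its path."""

    def _write(data, name="vol.nii.gz", affine=None):
        path = tmp_path / name
        nib.save(nib.Nifti1Image(np.asarray(data), affine if affine is not None else np.eye(4)),
                 str(path))
        return path

    return _write


def mask_of(data, affine=None):
    return AnalysisMask(np.asarray(data, dtype=bool),
                        affine if affine is not None else np.eye(4))
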