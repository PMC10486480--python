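import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nphct import features, phantom

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synthetic_cohort_features():
    """Feature matrix and labels for the 100+100 shipped-preset cohort, seed 42.

    Shared across the classifier-level tests so the (few-second) phantom
    generation runs once per session.
    """
    cohort = phantom.generate_cohort(100, 100, seed=42)
    X, y = features.cohort_feature_matrix(cohort)
    return X, y


@pytest.fixture(scope="session")
def preset_pair():
    """One normal and one NPH phantom generated with the same seed."""
    normal = phantom.generate_label_volume(phantom.NORMAL_PRESET.replace(seed=5))
    nph = phantom.generate_label_volume(phantom.NPH_PRESET.replace(seed=5))
    return normal, nph


def make_label_volume(n_brain_slices: int, shape_yx=(8, 8), csf_per_slice=2):
    """Small handmade volume with brain in exactly `n_brain_slices` slices."""
    nz = n_brain_slices + 2
    labels = np.zeros((nz, *shape_yx), dtype=np.uint8)
    for i in range(1, 1 + n_brain_slices):
        labels[i, :, :] = phantom.WHITE_GREY
        labels[i, 0, :csf_per_slice] = phantom.CSF
    return phantom.LabelVolume(labels=labels, voxel_spacing=(1, 1, 1))
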