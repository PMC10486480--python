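import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_label_volume
from nphct import features, phantom
from nphct.errors import DegenerateInputError, ParameterError


class TestCountSlice:
    def test_mixed_slice(self):
        arr = np.zeros((4, 4), dtype=np.uint8)
        arr.flat[:2] = phantom.CSF
        arr.flat[2:8] = phantom.WHITE_GREY
        c = features.count_slice(arr)
        assert (c.n_csf, c.n_wg, c.image_size) == (2, 6, 16)

    def test_all_background(self):
        c = features.count_slice(np.zeros((5, 5), dtype=np.uint8))
        assert (c.n_csf, c.n_wg, c.image_size) == (0, 0, 25)
        assert not c.has_brain

    def test_counts_exceeding_slice_rejected(self):
        with pytest.raises(ParameterError):
            features.SliceCounts(n_csf=10, n_wg=10, image_size=16)


class TestAssignPartitions:
    def test_identity_when_n_equals_k(self):
        scheme = features.assign_partitions(make_label_volume(10), k=10)
        assert scheme.partition_ids == tuple(range(10))

    def test_two_slices_per_partition(self):
        scheme = features.assign_partitions(make_label_volume(20), k=10)
        sizes = [scheme.partition_ids.count(p) for p in range(10)]
        assert sizes == [2] * 10
        assert scheme.partition_ids == tuple(sorted(scheme.partition_ids))

    def test_43_slices_matches_floor_rule(self):
        scheme = features.assign_partitions(make_label_volume(43), k=10)
        expected = tuple(10 * i // 43 for i in range(43))
        assert scheme.partition_ids == expected
        sizes = [scheme.partition_ids.count(p) for p in range(10)]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 43

    def test_too_few_brain_slices_rejected(self):
        with pytest.raises(DegenerateInputError):
            features.assign_partitions(make_label_volume(7), k=10)

    @given(n=st.integers(min_value=10, max_value=120))
    def test_partition_sizes_balanced_and_contiguous(self, n):
        scheme = features.assign_partitions(make_label_volume(n), k=10)
        ids = scheme.partition_ids
        assert len(ids) == n
        assert ids == tuple(sorted(ids))  # contiguous, nondecreasing
        sizes = [ids.count(p) for p in range(10)]
        assert max(sizes) - min(sizes) <= 1

    def test_empty_slices_excluded(self):
        vol = make_label_volume(12)
        vol.labels[5] = phantom.BACKGROUND  # punch a gap
        scheme = features.assign_partitions(vol, k=10)
        assert 5 not in scheme.slice_indices
        assert len(scheme.slice_indices) == 11


class TestSliceRatios:
    def test_direct_formulas(self):
        r = features.slice_ratios(features.SliceCounts(50, 150, 4096))
        assert r == (0.25, 50 / 150, 50 / 4096, 150 / 4096)

    def test_empty_slice_convention(self):
        assert features.slice_ratios(features.SliceCounts(0, 0, 4096)) == (0, 0, 0, 0)

    def test_wg_zero_cap(self):
        r = features.slice_ratios(features.SliceCounts(10, 0, 4096), wg_zero_cap=1e6)
        assert r[0] == 1.0 and r[1] == 1e6

    @given(n_csf=st.integers(0, 500), n_wg=st.integers(1, 500))
    def test_ratio_identity(self, n_csf, n_wg):
        csf_ratio, csf_wg, _, _ = features.slice_ratios(
            features.SliceCounts(n_csf, n_wg, 1024)
        )
        assert csf_ratio == pytest.approx(csf_wg / (1 + csf_wg))


class TestAggregate:
    def test_constant(self):
        mean, mn, mx, std = features.aggregate([0.2, 0.2, 0.2])
        assert (mean, mn, mx) == (pytest.approx(0.2),) * 3
        assert std == pytest.approx(0.0, abs=1e-15)

    def test_two_point_closed_form(self):
        assert features.aggregate([0.0, 1.0]) == (0.5, 0.0, 1.0, 0.5)

    def test_against_brute_force_oracle(self):
        vals = [0.1, 0.2, 0.3, 0.6]
        mean, mn, mx, std = features.aggregate(vals)
        m = sum(vals) / len(vals)
        oracle_std = math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))
        assert mean == pytest.approx(0.3)
        assert std == pytest.approx(oracle_std) == pytest.approx(math.sqrt(0.035))

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            features.aggregate([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_min_mean_max_ordering(self, vals):
        mean, mn, mx, std = features.aggregate(vals)
        assert mn <= mean + 1e-12 and mean <= mx + 1e-12 and std >= 0


class TestExtractFeatures:
    def test_uniform_volume_collapses(self):
        vol = make_label_volume(20, shape_yx=(6, 6), csf_per_slice=3)
        f = features.extract_features(vol)
        slice_ratio = 3 / 36
        assert f["CSF_ratio_all"] == pytest.approx(slice_ratio)
        assert f["Mean CSF ratio_all"] == pytest.approx(slice_ratio)
        assert f["Std CSF ratio_all"] == pytest.approx(0.0, abs=1e-12)
        for p in range(10):
            assert f[f"CSF ratio_{p}"] == pytest.approx(slice_ratio)
            assert f[f"Std CSF ratio_{p}"] == pytest.approx(0.0, abs=1e-12)

    def test_feature_names_exact_and_complete(self):
        names = features.feature_names()
        assert len(names) == 132
        for required in ("CSF ratio_5", "Std CSF ratio_9", "CSF_ratio_all"):
            assert required in names
        vol = make_label_volume(15)
        f = features.extract_features(vol)
        assert list(f.index) == names

    def test_pooled_ratio_within_slice_extremes(self):
        cohort = phantom.generate_cohort(2, 2, seed=9)
        for vol, _ in cohort:
            f = features.extract_features(vol)
            for p in range(10):
                assert (
                    f[f"Min CSF ratio_{p}"] - 1e-12
                    <= f[f"CSF ratio_{p}"]
                    <= f[f"Max CSF ratio_{p}"] + 1e-12
                )

    def test_min_mean_max_families_ordered(self):
        vol = phantom.generate_label_volume(phantom.NPH_PRESET.replace(seed=13))
        f = features.extract_features(vol)
        for stem in ("CSF ratio", "CSF/WG ratio"):
            for p in [str(i) for i in range(10)] + ["all"]:
                sep = "_"
                assert f[f"Min {stem}{sep}{p}"] <= f[f"Mean {stem}{sep}{p}"] + 1e-12
                assert f[f"Mean {stem}{sep}{p}"] <= f[f"Max {stem}{sep}{p}"] + 1e-12

    def test_csf_plus_brain_size_bounded(self):
        vol = phantom.generate_label_volume(phantom.NORMAL_PRESET.replace(seed=2))
        counts = features.slice_counts(vol)
        for c in counts:
            if c.has_brain:
                _, _, csf_size, brain_size = features.slice_ratios(c)
                assert csf_size + brain_size <= 1.0 + 1e-12

    def test_ventricle_scale_raises_mid_partition_ratio(self):
        lo = phantom.generate_label_volume(
            phantom.PhantomParams(ventricle_scale=1.0, sulcal_scale=0.5, seed=6)
        )
        hi = phantom.generate_label_volume(
            phantom.PhantomParams(ventricle_scale=1.8, sulcal_scale=0.5, seed=6)
        )
        flo, fhi = features.extract_features(lo), features.extract_features(hi)
        assert fhi["CSF ratio_5"] > flo["CSF ratio_5"]
        assert fhi["CSF ratio_4"] > flo["CSF ratio_4"]

    def test_cohort_matrix_shape(self):
        cohort = phantom.generate_cohort(2, 3, seed=1)
        X, y = features.cohort_feature_matrix(cohort)
        assert X.shape == (5, 132)
        assert list(y) == [1, 1, 0, 0, 0]
        assert np.isfinite(X.to_numpy()).all()
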