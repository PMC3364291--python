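import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import devvar as dv

from conftest import make_matrix, make_samples


class TestDetectionFilter:
    def test_counts_detected_subjects_per_probe(self):
        detection = [
            [0.05, 0.05, 0.5, 0.5],
            [0.2, 0.2, 0.2, 0.05],
            [0.09, 0.10, 0.11, 0.12],
        ]
        m = make_matrix(np.ones((3, 4)), scale="raw", detection=detection)
        s = make_samples([1, 2, 3, 20])
        out = dv.filter_by_detection(m, p_threshold=0.1, min_individuals=2, samples=s)
        assert out.probe_ids == ["P000", "P002"]

    def test_all_detected_keeps_everything(self):
        m = make_matrix(np.ones((3, 4)), scale="raw", detection=np.zeros((3, 4)))
        s = make_samples([1, 2, 3, 20])
        out = dv.filter_by_detection(m, 0.1, 4, s)
        assert out.n_probes == 3

    def test_any_replicate_vote_counts_subject_once(self):
        # one subject on two arrays: detected on one array suffices
        detection = [[0.05, 0.9, 0.9]]
        m = make_matrix([[1.0, 1.0, 1.0]], scale="raw", detection=detection)
        s = make_samples([3, 3, 20], subjects=["A", "A", "B"])
        assert dv.filter_by_detection(m, 0.1, 1, s).n_probes == 1
        out_all = dv.filter_by_detection(m, 0.1, 1, s, vote="all")
        assert out_all.n_probes == 0

    def test_requires_detection_p(self):
        m = make_matrix(np.ones((2, 3)), scale="raw")
        with pytest.raises(ValueError, match="detection"):
            dv.filter_by_detection(m, 0.1, 1, make_samples([1, 2, 20]))


class TestOffsetLog2:
    def test_hand_example(self):
        m = make_matrix([[-3.0], [1.0], [7.0]], sample_ids=["a"], scale="raw")
        # bypass the 2-sample QN requirement; offset acts globally
        out = dv.offset_and_log2(m)
        np.testing.assert_allclose(
            out.values.to_numpy().ravel(), [0.0, 2.321928, 3.459432], atol=1e-6
        )

    def test_minimum_already_one_is_pure_log2(self):
        m = make_matrix([[1.0, 4.0], [2.0, 8.0]], scale="raw")
        out = dv.offset_and_log2(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[0, 2], [1, 3]])

    @given(
        arrays(
            float,
            (4, 3),
            elements=st.floats(-100, 1e4, allow_nan=False, width=32),
        )
    )
    def test_minimum_of_output_is_zero(self, x):
        out = dv.offset_and_log2(make_matrix(x, scale="raw"))
        assert out.values.to_numpy().min() == pytest.approx(0.0, abs=1e-9)
        assert out.scale == "log2"


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        m = make_matrix([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        out = dv.quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_example(self):
        m = make_matrix(np.array([[2.0, 5.0], [4.0, 3.0], [6.0, 1.0]]))
        out = dv.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 5.5])
        np.testing.assert_allclose(out[:, 1], [5.5, 3.5, 1.5])

    def test_tie_rule_averages_reference_values(self):
        m = make_matrix(np.array([[1.0, 2.0], [1.0, 4.0], [3.0, 6.0]]))
        out = dv.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 2.5, 4.5])

    @given(
        arrays(
            float,
            (6, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
            unique=True,
        )
    )
    def test_idempotent_and_columns_share_distribution(self, x):
        # tie-free columns: with ties the map is only idempotent once the
        # tie-averaged values have become the column values
        once = dv.quantile_normalize(make_matrix(x))
        twice = dv.quantile_normalize(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9
        )
        sums = once.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(sums, sums[0], atol=1e-8)

    def test_rejects_missing_values(self):
        m = make_matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            dv.quantile_normalize(m)


class TestAverageReplicates:
    def test_no_duplicates_is_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        s = make_samples([3, 20])
        out, out_s = dv.average_technical_replicates(m, s)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_arithmetic_mean_of_replicates(self):
        m = make_matrix([[2.0, 4.0], [4.0, 6.0]])
        s = make_samples([3, 3], subjects=["A", "A"])
        out, out_s = dv.average_technical_replicates(m, s)
        np.testing.assert_allclose(out.values.to_numpy().ravel(), [3.0, 5.0])
        assert out.sample_ids == ["A"]
        assert out_s.sample_ids == ["A"]

    def test_forty_arrays_collapse_to_37_subjects(self, small_study):
        matrix, samples, _ = small_study
        assert matrix.n_samples == 40
        out, out_s = dv.average_technical_replicates(matrix, samples)
        assert out.n_samples == 37
        assert out_s.n_subjects == 37

    def test_conflicting_covariates_error_names_subject(self):
        m = make_matrix([[1.0, 2.0]])
        s = make_samples([3, 4], subjects=["A", "A"])
        with pytest.raises(ValueError, match="'A'"):
            dv.average_technical_replicates(m, s)


class TestAdjustGroupMeans:
    def test_single_level_centers_rows(self):
        m = make_matrix([[1.0, 3.0, 5.0]])
        s = make_samples([1, 2, 3], sexes=["male"] * 3)
        out = dv.adjust_group_means(m, s, "sex")
        np.testing.assert_allclose(out.values.to_numpy().ravel(), [-2, 0, 2])

    def test_two_level_hand_example(self):
        m = make_matrix([[1.0, 3.0, 2.0, 6.0]])
        s = make_samples([1, 2, 3, 4], sexes=["male", "male", "female", "female"])
        out = dv.adjust_group_means(m, s, "sex")
        np.testing.assert_allclose(out.values.to_numpy().ravel(), [-1, 1, -2, 2])

    def test_level_means_zero_and_within_level_variance_kept(self, small_study):
        matrix, samples, _ = small_study
        log2 = dv.offset_and_log2(matrix)
        out = dv.adjust_group_means(log2, samples, "sex")
        for lev in ("male", "female"):
            cols = samples.data.index[samples.data["sex"] == lev]
            if len(cols) == 0:
                continue
            means = out.values[cols].mean(axis=1).to_numpy()
            np.testing.assert_allclose(means, 0.0, atol=1e-12)
            np.testing.assert_allclose(
                out.values[cols].var(axis=1, ddof=1),
                log2.values[cols].var(axis=1, ddof=1),
                rtol=1e-10,
            )
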