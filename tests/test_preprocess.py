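"""Preprocessing contracts: replicate averaging, normalization, exclusions,
class merging, detectability filtering, profiles and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from mirtoo.matrix import ExpressionMatrix, MatrixError
from mirtoo.panel import DEFAULT_PANEL, HISTOLOGICAL_CLASSES
from mirtoo.preprocess import (
    average_replicates,
    class_mean_profiles,
    detectability_filter,
    exclude_mirnas,
    hierarchical_cluster,
    log_transform,
    merge_classes,
    normalize_median,
)


def _meta_for(matrix, patient_ids=None, role="reference_primary", labels=None):
    ids = matrix.sample_ids
    return pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": patient_ids or ids,
            "sex": "female",
            "role": role,
            "class_label": labels or ["LUAD"] * len(ids),
            "biopsy_site": "primary",
            "time_months": np.nan,
            "event": np.nan,
        }
    )


class TestAverageReplicates:
    def test_arithmetic_mean_of_replicate_rows(self):
        m = ExpressionMatrix(
            pd.DataFrame([[2.0, 4.0], [4.0, 8.0]], index=["a", "b"],
                         columns=["m1", "m2"])
        )
        meta = _meta_for(m, patient_ids=["p1", "p1"])
        out, out_meta = average_replicates(m, meta)
        assert out.shape == (1, 2)
        assert list(out.data.iloc[0]) == [3.0, 6.0]
        assert len(out_meta) == 1

    def test_no_replicates_is_identity(self, small_matrix):
        meta = _meta_for(small_matrix)
        out, _ = average_replicates(small_matrix, meta)
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_after_normalization_is_error(self, small_matrix):
        meta = _meta_for(small_matrix)
        with pytest.raises(MatrixError, match="before normalization"):
            average_replicates(normalize_median(small_matrix), meta)

    def test_cross_label_averaging_is_error(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["m1"])
        )
        meta = _meta_for(m, patient_ids=["p1", "p1"], labels=["LUAD", "PAAD"])
        with pytest.raises(MatrixError, match="different class labels"):
            average_replicates(m, meta)

    def test_metastases_of_one_patient_stay_separate(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["m1"])
        )
        meta = _meta_for(m, patient_ids=["p1", "p1"], role="cup")
        meta["class_label"] = np.nan
        out, _ = average_replicates(m, meta)
        assert out.shape == (2, 1)


class TestNormalizeMedian:
    def test_divides_by_sample_median(self, small_matrix):
        out = normalize_median(small_matrix)
        assert list(out.data.loc["s1"]) == [0.5, 1.0, 1.5]
        assert list(out.data.loc["s2"]) == [1.0, 1.0, 1.0]
        assert out.normalized

    def test_every_sample_median_becomes_one(self, reference_cohort):
        _, matrix, _ = reference_cohort
        out = normalize_median(matrix)
        med = np.median(out.data.to_numpy(), axis=1)
        assert np.allclose(med, 1.0, atol=1e-9)

    def test_renormalizing_flagged_matrix_is_error(self, small_matrix):
        with pytest.raises(MatrixError, match="already normalized"):
            normalize_median(normalize_median(small_matrix))

    def test_zero_median_names_the_sample(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 0.0, 1.0]], index=["bad"], columns=list("abc"))
        )
        with pytest.raises(MatrixError, match="bad"):
            normalize_median(m)


class TestLogTransform:
    def test_closed_form_values(self, small_matrix):
        out = log_transform(normalize_median(small_matrix))
        assert out.data.loc["s2", "miR-a"] == pytest.approx(np.log2(1.01))
        assert out.log_transformed

    def test_zero_maps_to_log2_pseudocount(self):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 1.0, 2.0]], index=["s"], columns=list("abc"))
        )
        out = log_transform(normalize_median(m))
        assert out.data.loc["s", "a"] == pytest.approx(np.log2(0.01))

    def test_requires_normalized_and_forbids_double(self, small_matrix):
        with pytest.raises(MatrixError, match="normalized"):
            log_transform(small_matrix)
        once = log_transform(normalize_median(small_matrix))
        with pytest.raises(MatrixError, match="already log-transformed"):
            log_transform(once)

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 100, 50))
        m = ExpressionMatrix(
            pd.DataFrame([x], index=["s"], columns=[f"m{i}" for i in range(50)])
        )
        out = log_transform(normalize_median(m))
        assert (np.diff(out.data.loc["s"].to_numpy()) >= 0).all()


class TestExcludeMirnas:
    def test_default_list_leaves_87_of_89(self, reference_cohort):
        _, matrix, _ = reference_cohort
        out = exclude_mirnas(matrix)
        assert out.shape[1] == 87
        assert "miR-122-5p" not in out.mirna_ids
        assert "miR-21-5p" not in out.mirna_ids

    def test_empty_list_is_identity(self, small_matrix):
        out = exclude_mirnas(small_matrix, [])
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_double_exclusion_is_error(self, reference_cohort):
        _, matrix, _ = reference_cohort
        once = exclude_mirnas(matrix)
        with pytest.raises(MatrixError, match="not in panel"):
            exclude_mirnas(once)


class TestMergeClasses:
    @pytest.mark.parametrize(
        "raw, merged",
        [("STAD", "STAD-CRC"), ("CRC", "STAD-CRC"), ("KIRP", "KICA"),
         ("KIRC", "KICA"), ("LUAD", "LUAD")],
    )
    def test_examples(self, raw, merged):
        assert merge_classes([raw])[0] == merged

    def test_nineteen_labels_collapse_to_seventeen(self):
        merged = merge_classes(list(HISTOLOGICAL_CLASSES))
        assert merged.nunique() == 17

    def test_idempotent(self):
        once = merge_classes(list(HISTOLOGICAL_CLASSES))
        twice = merge_classes(once)
        assert list(once) == list(twice)

    def test_unknown_label_raises(self):
        with pytest.raises(MatrixError, match="outside the class map"):
            merge_classes(["NOTACLASS"])


class TestDetectabilityFilter:
    def test_sample_missing_half_the_panel_dropped(self):
        data = pd.DataFrame(
            np.ones((3, 10)), index=list("abc"),
            columns=[f"m{i}" for i in range(10)],
        )
        data.iloc[0, :5] = np.nan
        out = detectability_filter(ExpressionMatrix(data), sample_frac=0.8)
        assert "a" not in out.sample_ids

    def test_fully_observed_matrix_unchanged(self, small_matrix):
        out = detectability_filter(small_matrix)
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_output_has_no_missing_values(self, rng):
        data = pd.DataFrame(
            rng.uniform(1, 10, (20, 15)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"m{i}" for i in range(15)],
        )
        mask = rng.random((20, 15)) < 0.15
        data[mask] = np.nan
        out = detectability_filter(ExpressionMatrix(data))
        assert not out.data.isna().any().any()

    def test_matches_bruteforce_rule_application(self, rng):
        """Surviving rows/columns equal exhaustive application of the two
        rules in order on a crafted 10x10 missingness pattern."""
        data = pd.DataFrame(
            rng.uniform(1, 10, (10, 10)),
            index=[f"s{i}" for i in range(10)],
            columns=[f"m{i}" for i in range(10)],
        )
        mask = rng.random((10, 10)) < 0.25
        data[mask] = np.nan
        out = detectability_filter(ExpressionMatrix(data), sample_frac=0.8)
        keep_samples = [
            s for s in data.index if data.loc[s].notna().sum() >= 8
        ]
        keep_mirnas = [
            m for m in data.columns if data.loc[keep_samples, m].notna().all()
        ]
        assert out.sample_ids == keep_samples
        assert out.mirna_ids == keep_mirnas

    def test_all_samples_removed_is_error(self):
        data = pd.DataFrame(np.nan, index=["a"], columns=["m1", "m2"])
        with pytest.raises(MatrixError, match="every sample"):
            detectability_filter(ExpressionMatrix(data))


class TestClassMeanProfiles:
    def test_hand_example(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 3.0], [3.0, 5.0]], index=["a", "b"],
                         columns=["m1", "m2"])
        )
        means, sds = class_mean_profiles(m, ["k", "k"])
        assert list(means.loc["k"]) == [2.0, 4.0]
        assert np.allclose(sds.loc["k"], np.sqrt(2.0))

    def test_singleton_class_has_undefined_sd(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["m1"])
        )
        means, sds = class_mean_profiles(m, ["x", "y"])
        assert means.loc["x", "m1"] == 1.0
        assert sds.loc["x"].isna().all()

    def test_agrees_with_independent_summation(self, reference_cohort, rng):
        _, matrix, meta = reference_cohort
        labels = meta.set_index("sample_id").loc[matrix.sample_ids, "class_label"]
        means, _ = class_mean_profiles(matrix, labels)
        cls = labels.iloc[0]
        ids = labels.index[labels == cls]
        manual = sum(matrix.data.loc[s].to_numpy() for s in ids) / len(ids)
        assert np.allclose(means.loc[cls].to_numpy(), manual, atol=1e-12)


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        dend = hierarchical_cluster(profiles)
        first = dend.merges[0]
        assert (first[0], first[1]) == (0, 1)
        assert first[2] == 0.0

    def test_manhattan_distance_arithmetic(self):
        profiles = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["a", "b"])
        dend = hierarchical_cluster(profiles)
        assert dend.merges[0][2] == 4.0

    def test_four_point_merge_sequence_matches_bruteforce(self, rng):
        """Complete-linkage merge order on a 4-point instance equals a
        brute-force enumeration over all cluster pairs."""
        X = rng.uniform(0, 10, (4, 3))
        profiles = pd.DataFrame(X, index=list("abcd"))
        dend = hierarchical_cluster(profiles)
        # brute force: track clusters as frozensets of leaves
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        clusters = {i: {i} for i in range(4)}
        expected = []
        nid = 4
        while len(clusters) > 1:
            best = None
            for (i, a), (j, b) in itertools.combinations(clusters.items(), 2):
                h = max(D[x, y] for x in a for y in b)
                key = (h, min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
            (h, lo, hi), i, j = best
            expected.append((lo, hi, h))
            clusters[nid] = clusters.pop(i) | clusters.pop(j)
            nid += 1
        got = [(m[0], m[1], m[2]) for m in dend.merges]
        assert got == pytest.approx(expected)

    def test_matches_scipy_on_tie_free_instances(self, rng):
        for _ in range(5):
            X = rng.normal(size=(7, 4))
            profiles = pd.DataFrame(X, index=[f"c{i}" for i in range(7)])
            ours = hierarchical_cluster(profiles).to_linkage()
            ref = linkage(pdist(X, metric="cityblock"), method="complete")
            assert np.allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]), atol=1e-10)

    def test_correlation_metric_available(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]],
            index=list("abc"),
        )
        dend = hierarchical_cluster(profiles, metric="correlation")
        first = dend.merges[0]
        assert (first[0], first[1]) == (0, 1)  # perfectly correlated pair
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_profile_rejected(self):
        with pytest.raises(MatrixError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]], index=["a"]))
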