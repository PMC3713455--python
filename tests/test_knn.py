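import math

import numpy as np
import pandas as pd
import pytest

import kdsig
from kdsig.knn import LABEL_CONTROL, LABEL_DRIVER_LOW
from conftest import make_matrix


def knn_oracle(train_z, labels, test_z, k):
    """Plain-Python all-pairs distance scan with majority vote."""
    out = {}
    for s in test_z.columns:
        dists = []
        for t in train_z.columns:
            d = math.sqrt(sum((test_z[s][g] - train_z[t][g]) ** 2 for g in train_z.index))
            dists.append((d, t))
        dists.sort()
        kk = k
        while kk < len(dists) and dists[kk][0] == dists[kk - 1][0]:
            kk += 1
        votes = {}
        for _, t in dists[:kk]:
            votes[labels[t]] = votes.get(labels[t], 0) + 1
        label = max(sorted(votes), key=lambda l: votes[l])
        out[s] = (label, votes[label] / kk)
    return out


@pytest.fixture
def training_set(kd_series, refined_signature):
    series, _ = kd_series
    return kdsig.build_training_set(series, refined_signature)


class TestBuildTrainingSet:
    def test_label_mapping_from_groups(self, training_set):
        counts = training_set.labels.value_counts()
        assert counts[LABEL_DRIVER_LOW] == 8
        assert counts[LABEL_CONTROL] == 5  # 4 control-shRNA + 1 unperturbed

    def test_stored_means_match_training_rows(self, training_set):
        recomputed = training_set.features.mean(axis=1)
        pd.testing.assert_series_equal(training_set.gene_means, recomputed)

    def test_absent_genes_reduce_coverage(self, kd_series, refined_signature):
        series, _ = kd_series
        genes = refined_signature.positive_genes + ["NOT_A_GENE"]
        training = kdsig.build_training_set(series, genes)
        assert training.coverage == pytest.approx(len(genes[:-1]) / len(genes))

    def test_insufficient_coverage_rejected(self, kd_series):
        series, _ = kd_series
        genes = ["POS0001"] + [f"MISSING{i}" for i in range(9)]
        with pytest.raises(ValueError, match="signature genes present"):
            kdsig.build_training_set(series, genes)

    def test_zero_variance_gene_excluded_with_warning(self, kd_series):
        series, _ = kd_series
        values = series.values.copy()
        values.loc["POS0001"] = 5.0  # constant row
        flat = kdsig.ExpressionMatrix(values, series.sample_annotations)
        with pytest.warns(UserWarning, match="zero-variance"):
            training = kdsig.build_training_set(flat, ["POS0001", "POS0002", "POS0003"])
        assert "POS0001" not in training.features.index
        assert training.dropped_zero_variance == ["POS0001"]


class TestHarmonize:
    def test_identical_platform_coverage_one(self, training_set, default_cohort):
        cohort, _ = default_cohort
        pair = kdsig.harmonize(training_set, cohort)
        assert pair.coverage == 1.0
        np.testing.assert_allclose(pair.test.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(pair.test.std(axis=1, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pair.train.mean(axis=1), 0.0, atol=1e-12)

    def test_affine_distortion_cancelled(self, training_set, planted_signature, kd_series):
        series, _ = kd_series
        design = kdsig.CohortDesign(
            signature_genes=planted_signature,
            platform_distortion=kdsig.PlatformDistortion(scale_sd=0.2, offset_sd=1.0),
            seed=5,
        )
        cohort, _ = kdsig.simulate_patient_cohort(design, gene_ids=list(series.gene_ids))
        pair = kdsig.harmonize(training_set, cohort)
        np.testing.assert_allclose(pair.test.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(pair.test.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_low_coverage_errors(self, training_set, default_cohort):
        cohort, _ = default_cohort
        n_keep = max(3, int(0.3 * len(training_set.features.index)))
        keep = list(training_set.features.index[:n_keep]) + ["G00001"]
        subset = kdsig.ExpressionMatrix(
            cohort.values.loc[cohort.values.index.intersection(keep)],
            cohort.sample_annotations,
        )
        with pytest.raises(ValueError, match="coverage"):
            kdsig.harmonize(training_set, subset)


class TestKnnClassify:
    def test_exact_training_replica_recovers_labels(self, kd_series, training_set):
        """A test cohort of copied training samples maps back to its labels."""
        series, _ = kd_series
        copies = ["KD1", "KD2", "KD3", "KD4", "CTRL1", "CTRL2", "CTRL3", "CTRL4"]
        test = kdsig.ExpressionMatrix(
            series.values[copies].rename(columns=lambda c: c + "_copy")
        )
        res = kdsig.knn_classify(training_set, test, k=3)
        for c in copies:
            expected = LABEL_DRIVER_LOW if c.startswith("KD") else LABEL_CONTROL
            assert res.predictions.loc[c + "_copy", "label"] == expected

    def test_vote_arithmetic_two_of_three(self):
        # 2 control neighbors + 1 driver-low neighbor at equal-ish distance
        train = make_matrix(
            [[0.0, 0.1, 5.0, 5.1, 10.0]],
            genes=["g"],
            samples=["c1", "c2", "d1", "d2", "d3"],
            groups=["control-shRNA", "control-shRNA", "driver-shRNA",
                    "driver-shRNA", "driver-shRNA"],
        )
        # single gene: variance exists; use raw label mapping via TrainingSet
        training = kdsig.build_training_set(train, ["g"], min_coverage=0.0)
        test = make_matrix([[2.0]], genes=["g"], samples=["x"])
        res = kdsig.knn_classify(training, test, k=3)
        row = res.predictions.loc["x"]
        assert row["confidence"] in (2 / 3, 1.0)
        assert row["signed_score"] == (
            -row["confidence"] if row["label"] == LABEL_DRIVER_LOW else row["confidence"]
        )

    def test_confidence_values_are_vote_fractions(self, training_set, default_cohort):
        cohort, _ = default_cohort
        res = kdsig.knn_classify(training_set, cohort, k=3)
        assert set(res.predictions["confidence"].unique()) <= {2 / 3, 1.0}
        assert (res.predictions["confidence"] > 0.5).all()

    def test_matches_all_pairs_oracle(self, training_set):
        rng = np.random.default_rng(0)
        for trial in range(20):
            genes = list(training_set.features.index[:10])
            test = kdsig.ExpressionMatrix(
                pd.DataFrame(
                    rng.normal(7, 2, size=(len(genes), 4)),
                    index=genes,
                    columns=[f"t{j}" for j in range(4)],
                )
            )
            small = kdsig.TrainingSet(
                features=training_set.features.loc[genes],
                labels=training_set.labels,
                gene_means=training_set.gene_means[genes],
                gene_sds=training_set.gene_sds[genes],
                coverage=1.0,
            )
            res = kdsig.knn_classify(small, test, k=3)
            pair = kdsig.harmonize(small, test)
            expected = knn_oracle(pair.train, small.labels.to_dict(), pair.test, 3)
            for s, (label, conf) in expected.items():
                assert res.predictions.loc[s, "label"] == label
                assert res.predictions.loc[s, "confidence"] == pytest.approx(conf)

    def test_invariant_to_gene_and_sample_order(self, training_set, default_cohort):
        cohort, _ = default_cohort
        res = kdsig.knn_classify(training_set, cohort, k=3)
        shuffled = kdsig.ExpressionMatrix(
            cohort.values.iloc[::-1, ::-1], cohort.sample_annotations.iloc[::-1]
        )
        res2 = kdsig.knn_classify(training_set, shuffled, k=3)
        joined = res.predictions["label"].sort_index()
        joined2 = res2.predictions["label"].sort_index()
        pd.testing.assert_series_equal(joined, joined2)

    def test_k_equal_n_train_returns_majority_label(self, training_set, default_cohort):
        cohort, _ = default_cohort
        res = kdsig.knn_classify(training_set, cohort, k=training_set.n_samples)
        majority = training_set.labels.value_counts().idxmax()
        assert (res.predictions["label"] == majority).all()

    def test_distance_tie_expands_k(self):
        train = make_matrix(
            [[0.0, 2.0, -2.0, 4.0, 6.0]],
            genes=["g"],
            samples=["a", "b", "c", "d", "e"],
            groups=["driver-shRNA", "driver-shRNA", "control-shRNA",
                    "control-shRNA", "driver-shRNA"],
        )
        training = kdsig.build_training_set(train, ["g"], min_coverage=0.0)
        # after z-scoring, b and c are equidistant from a's position
        test = make_matrix([[0.0]], genes=["g"], samples=["x"])
        res = kdsig.knn_classify(training, test, k=2)
        assert len(res.predictions.loc["x", "neighbors"]) == 3

    def test_label_recovery_on_default_cohort(self, training_set, default_cohort):
        cohort, truth = default_cohort
        res = kdsig.knn_classify(training_set, cohort, k=3)
        want = truth.labels["label"].map(
            lambda l: LABEL_DRIVER_LOW if l == "driver-low" else LABEL_CONTROL
        )
        accuracy = (res.predictions["label"] == want).mean()
        assert accuracy >= 0.95

    def test_cross_platform_recovery_with_dropout(self, training_set, planted_signature, kd_series):
        """Affine distortion + 15% gene dropout still recovers >= 90% of labels."""
        series, _ = kd_series
        design = kdsig.CohortDesign(
            signature_genes=planted_signature,
            platform_distortion=kdsig.PlatformDistortion(
                scale_sd=0.15, offset_sd=1.0, dropout=0.15
            ),
            seed=9,
        )
        cohort, truth = kdsig.simulate_patient_cohort(
            design, gene_ids=list(series.gene_ids)
        )
        res = kdsig.knn_classify(training_set, cohort, k=3)
        want = truth.labels["label"].map(
            lambda l: LABEL_DRIVER_LOW if l == "driver-low" else LABEL_CONTROL
        )
        assert (res.predictions["label"] == want).mean() >= 0.90
        assert res.coverage < 1.0

    def test_non_euclidean_metric_rejected(self, training_set, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError, match="Euclidean"):
            kdsig.knn_classify(training_set, cohort, k=3, metric="manhattan")
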