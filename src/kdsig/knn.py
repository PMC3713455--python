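"""KNN classification of patient samples against knockdown-series profiles.

The training set is the knockdown series restricted to the refined
signature genes: driver-shRNA samples are the ``driver-low`` class,
control-shRNA and unperturbed samples the ``control`` class.  Before
classification the training and test matrices are harmonized to their
shared genes and each gene is z-scored within its own dataset — the
minimal transformation that makes Euclidean distances comparable across
platforms.  Each test sample is labeled by the majority vote of its
k = 3 nearest training samples; confidence is the vote fraction and the
signed score follows the convention that negative values mean the
signature (driver-low state) is present.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .matrix import (
    GROUP_CONTROL_SHRNA,
    GROUP_DRIVER_SHRNA,
    GROUP_UNPERTURBED,
    ExpressionMatrix,
)
from .signature import SignatureSet

logger = logging.getLogger(__name__)

LABEL_DRIVER_LOW = "driver-low"
LABEL_CONTROL = "control"

DEFAULT_K = 3
MIN_COVERAGE_ERROR = 0.5
MIN_COVERAGE_WARN = 0.8

_GROUP_TO_LABEL = {
    GROUP_DRIVER_SHRNA: LABEL_DRIVER_LOW,
    GROUP_CONTROL_SHRNA: LABEL_CONTROL,
    GROUP_UNPERTURBED: LABEL_CONTROL,
}


@dataclass
class TrainingSet:
    """Signature-gene training profiles with per-gene standardization."""

    features: pd.DataFrame  # genes x training samples (log2)
    labels: pd.Series  # per training sample
    gene_means: pd.Series
    gene_sds: pd.Series
    coverage: float  # fraction of requested signature genes present
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.features.shape[1]


def build_training_set(
    knockdown_matrix: ExpressionMatrix,
    signature: SignatureSet | list[str],
    min_coverage: float = MIN_COVERAGE_WARN,
) -> TrainingSet:
    """Restrict the knockdown series to signature genes and label samples."""
    genes = (
        signature.positive_genes if isinstance(signature, SignatureSet) else list(signature)
    )
    if not genes:
        raise ValueError("signature is empty")
    present = [g for g in genes if g in knockdown_matrix.values.index]
    coverage = len(present) / len(genes)
    if coverage < min_coverage:
        raise ValueError(
            f"only {coverage:.0%} of signature genes present "
            f"(minimum {min_coverage:.0%})"
        )
    if coverage < 1.0:
        logger.info(
            "%d of %d signature genes absent from the training matrix",
            len(genes) - len(present), len(genes),
        )

    knockdown_matrix.require_group_labels()
    labels = {}
    for s in knockdown_matrix.sample_ids:
        group = knockdown_matrix.groups[s]
        if group not in _GROUP_TO_LABEL:
            raise ValueError(f"sample {s!r} has non-training group {group!r}")
        labels[s] = _GROUP_TO_LABEL[group]
    labels = pd.Series(labels)
    if labels.nunique() != 2:
        raise ValueError("training set must contain both classes")

    features = knockdown_matrix.values.loc[present]
    sds = features.std(axis=1, ddof=1)
    dropped = list(features.index[sds == 0])
    if dropped:
        warnings.warn(f"excluding {len(dropped)} zero-variance training genes")
        features = features.drop(index=dropped)
        sds = sds.drop(index=dropped)
    return TrainingSet(
        features=features,
        labels=labels,
        gene_means=features.mean(axis=1),
        gene_sds=sds,
        coverage=coverage,
        dropped_zero_variance=dropped,
    )


@dataclass
class HarmonizedPair:
    """Training and test features aligned to shared genes, z-scored per dataset."""

    train: pd.DataFrame  # genes x train samples
    test: pd.DataFrame  # genes x test samples
    coverage: float


def harmonize(training: TrainingSet, test_matrix: ExpressionMatrix) -> HarmonizedPair:
    """Align feature spaces and z-score each gene within its own dataset.

    Training genes use the stored training mean/sd; test genes use the
    test cohort's own mean/sd, so cross-platform location and scale
    differences cancel.  Coverage below 0.5 is an error (classification
    would be unreliable); below 0.8 a warning is recorded.
    """
    shared = training.features.index.intersection(test_matrix.values.index)
    coverage = len(shared) / len(training.features.index)
    if coverage == 0:
        raise ValueError("no shared genes between training and test matrices")
    if coverage < MIN_COVERAGE_ERROR:
        raise ValueError(
            f"signature coverage on the test platform is {coverage:.0%} "
            f"(< {MIN_COVERAGE_ERROR:.0%}): classification unreliable"
        )
    if coverage < MIN_COVERAGE_WARN:
        warnings.warn(f"signature coverage on the test platform is {coverage:.0%}")

    train = training.features.loc[shared]
    train_z = train.sub(training.gene_means[shared], axis=0).div(
        training.gene_sds[shared], axis=0
    )
    test = test_matrix.values.loc[shared]
    test_sd = test.std(axis=1, ddof=1)
    # constant rows (or a single-sample cohort) scale by 1 instead of 0/NaN
    test_sd = test_sd.where(test_sd > 0, 1.0).fillna(1.0)
    test_z = test.sub(test.mean(axis=1), axis=0).div(test_sd, axis=0)
    return HarmonizedPair(train=train_z, test=test_z, coverage=coverage)


@dataclass
class ClassificationResult:
    """Per-sample KNN predictions with vote confidence and provenance."""

    predictions: pd.DataFrame  # label, confidence, signed_score, neighbors, distances
    coverage: float
    k: int

    def to_frame(self) -> pd.DataFrame:
        out = self.predictions.copy()
        out["neighbors"] = out["neighbors"].map(lambda ns: ",".join(ns))
        out["distances"] = out["distances"].map(
            lambda ds: ",".join(f"{d:.6g}" for d in ds)
        )
        out["coverage"] = self.coverage
        return out


def knn_classify(
    training: TrainingSet,
    test_matrix: ExpressionMatrix,
    k: int = DEFAULT_K,
    metric: str = "euclidean",
) -> ClassificationResult:
    """Classify test samples by majority vote of k nearest training samples.

    Predicted label is the majority among the k nearest (Euclidean)
    training profiles; confidence is the vote fraction (2/3 or 1.0 for
    binary k = 3); the signed score is -confidence for ``driver-low``
    and +confidence for ``control``.  A distance tie at the k-th
    position admits all tied neighbors, expanding k for that sample.
    """
    if metric != "euclidean":
        raise ValueError("only the Euclidean metric is supported")
    if not (1 <= k <= training.n_samples):
        raise ValueError(f"k must lie in [1, {training.n_samples}]")
    if k % 2 == 0:
        warnings.warn("even k can produce voting ties; prefer odd k")

    pair = harmonize(training, test_matrix)
    dist = cdist(pair.test.T.to_numpy(), pair.train.T.to_numpy(), metric="euclidean")
    train_samples = np.asarray(pair.train.columns)
    labels = training.labels[pair.train.columns].to_numpy()

    rows = []
    for i, sample in enumerate(pair.test.columns):
        d = dist[i]
        order = np.lexsort((train_samples, d))  # stable, deterministic ties
        kk = k
        while kk < len(d) and d[order[kk]] == d[order[kk - 1]]:
            kk += 1
        if kk != k:
            logger.info(
                "sample %s: distance tie at the k-th neighbor, k expanded to %d",
                sample, kk,
            )
        chosen = order[:kk]
        votes = pd.Series(labels[chosen]).value_counts()
        top = votes.max()
        winners = sorted(votes.index[votes == top])
        label = winners[0]  # deterministic; unreachable tie for odd k, 2 classes
        confidence = top / kk
        signed = -confidence if label == LABEL_DRIVER_LOW else confidence
        rows.append(
            {
                "sample": sample,
                "label": label,
                "confidence": confidence,
                "signed_score": signed,
                "neighbors": list(train_samples[chosen]),
                "distances": [float(x) for x in d[chosen]],
            }
        )
    predictions = pd.DataFrame(rows).set_index("sample")
    return ClassificationResult(predictions=predictions, coverage=pair.coverage, k=k)
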