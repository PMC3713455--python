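"""Two-class marker selection with permutation significance.

The per-gene statistic is the signal-to-noise ratio (SNR)

    score = (mu_A - mu_B) / (sigma_A + sigma_B)

with each class standard deviation floored at ``max(0.2 * |mu|, 0.2)``,
the convention of the comparative-marker tool family used for
microarray class comparisons.  Significance comes from two-sided label
permutations; when the number of distinct class assignments is small
enough the permutation null is enumerated exhaustively.  Genes are
filtered jointly on FDR (Benjamini-Hochberg over permutation p-values)
and linear-scale fold change.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

SIGMA_FLOOR_FRACTION = 0.2
SIGMA_FLOOR_MIN = 0.2

DEFAULT_Q_MAX = 0.006
DEFAULT_FC_MIN = 2.0
DEFAULT_N_PERM = 10_000

_PERM_BLOCK = 500  # permutations per vectorized block


def _two_class_masks(labels: pd.Series | np.ndarray, sample_ids) -> tuple[np.ndarray, list]:
    labels = pd.Series(np.asarray(labels, dtype=object), index=sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a class label")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    mask_a = (labels == classes[0]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int((~mask_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each class needs at least two samples")
    return mask_a, classes


def _snr_for_masks(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """SNR scores for many class-A masks at once.

    ``values`` is genes x samples; ``masks`` is perms x samples boolean.
    Returns genes x perms.
    """
    m = masks.T.astype(float)  # samples x perms
    n_a = masks.sum(axis=1).astype(float)  # per perm
    n_b = masks.shape[1] - n_a
    s = values @ m
    s2 = (values**2) @ m
    tot = values.sum(axis=1, keepdims=True)
    tot2 = (values**2).sum(axis=1, keepdims=True)
    mu_a = s / n_a
    mu_b = (tot - s) / n_b
    # unbiased per-class variance, clipped against tiny negatives
    var_a = np.clip((s2 - n_a * mu_a**2) / (n_a - 1), 0.0, None)
    var_b = np.clip((tot2 - s2 - n_b * mu_b**2) / (n_b - 1), 0.0, None)
    sd_a = np.maximum(np.sqrt(var_a), np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_a), SIGMA_FLOOR_MIN))
    sd_b = np.maximum(np.sqrt(var_b), np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_b), SIGMA_FLOOR_MIN))
    return (mu_a - mu_b) / (sd_a + sd_b)


def snr_scores(matrix: ExpressionMatrix, labels) -> pd.Series:
    """Observed SNR score per gene (class A = lexicographically first)."""
    mask_a, _ = _two_class_masks(labels, matrix.sample_ids)
    scores = _snr_for_masks(matrix.values.to_numpy(), mask_a[None, :])[:, 0]
    return pd.Series(scores, index=matrix.gene_ids)


def fold_change(matrix: ExpressionMatrix, labels) -> pd.DataFrame:
    """Linear-scale fold change per gene between the two classes.

    The ratio of de-logged class means is folded to >= 1 and reported
    with its direction (``up``: class A above class B).
    """
    mask_a, classes = _two_class_masks(labels, matrix.sample_ids)
    linear = np.exp2(matrix.values.to_numpy())
    mean_a = linear[:, mask_a].mean(axis=1)
    mean_b = linear[:, ~mask_a].mean(axis=1)
    ratio = mean_a / mean_b
    folded = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1.0, "up", "down")
    return pd.DataFrame(
        {"fold_change": folded, "direction": direction}, index=matrix.gene_ids
    )


def _permutation_masks_exhaustive(n: int, n_a: int) -> np.ndarray:
    masks = np.zeros((comb(n, n_a), n), dtype=bool)
    for i, idx in enumerate(combinations(range(n), n_a)):
        masks[i, list(idx)] = True
    return masks


def marker_scores(
    matrix: ExpressionMatrix,
    labels,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Score every gene for two-class differential expression.

    Returns a DataFrame indexed by gene with columns ``score``,
    ``fold_change``, ``direction``, ``p_perm`` and ``q``.  p-values are
    two-sided: the fraction of permuted |score| at least as large as the
    observed |score|, with the +1 finite-sample correction for sampled
    permutations.  When the number of distinct class assignments does
    not exceed ``n_perm`` the null is enumerated exhaustively (the
    identity assignment keeps p >= 1/total).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    mask_a, classes = _two_class_masks(labels, matrix.sample_ids)
    values = matrix.values.to_numpy()
    n = values.shape[1]
    n_a = int(mask_a.sum())

    observed = _snr_for_masks(values, mask_a[None, :])[:, 0]
    abs_obs = np.abs(observed)

    n_distinct = comb(n, n_a)
    exceed = np.zeros(values.shape[0], dtype=np.int64)
    if n_distinct <= n_perm:
        masks = _permutation_masks_exhaustive(n, n_a)
        for start in range(0, masks.shape[0], _PERM_BLOCK):
            block = masks[start : start + _PERM_BLOCK]
            perm = np.abs(_snr_for_masks(values, block))
            exceed += (perm >= abs_obs[:, None]).sum(axis=1)
        p = exceed / n_distinct
        logger.info("exhaustive permutation null (%d assignments)", n_distinct)
    else:
        rng = np.random.default_rng(seed)
        done = 0
        while done < n_perm:
            b = min(_PERM_BLOCK, n_perm - done)
            block = np.zeros((b, n), dtype=bool)
            for i in range(b):
                block[i, rng.choice(n, size=n_a, replace=False)] = True
            perm = np.abs(_snr_for_masks(values, block))
            exceed += (perm >= abs_obs[:, None]).sum(axis=1)
            done += b
        p = (1 + exceed) / (n_perm + 1)

    q = multipletests(p, method="fdr_bh")[1]
    fc = fold_change(matrix, labels)
    return pd.DataFrame(
        {
            "score": observed,
            "fold_change": fc["fold_change"],
            "direction": fc["direction"],
            "p_perm": p,
            "q": q,
        },
        index=matrix.gene_ids,
    )


def select_differential(
    results: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    fc_min: float = DEFAULT_FC_MIN,
) -> list[str]:
    """Genes with q <= q_max and fold change >= fc_min, by |score| desc."""
    keep = results[(results["q"] <= q_max) & (results["fold_change"] >= fc_min)]
    ordered = keep.reindex(
        keep["score"].abs().sort_values(ascending=False, kind="mergesort").index
    )
    return list(ordered.index)
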