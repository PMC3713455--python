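"""Derivation and refinement of the driver-correlated gene signature.

Every gene in the (filtered) knockdown series is scored by the Pearson
correlation of its cross-sample profile with the driver's profile; the
unrefined signature is the set of genes beyond a +/- cutoff (default
0.8, strict inequality).  Refinement then (i) removes positive members
that hierarchically cluster with the negatively correlated genes
(distance 1 - Pearson, average linkage; the negatives' cluster is the
smallest dendrogram node containing all of them) and (ii) removes
positive members with low expression in at least 75% of control
samples.  The refined signature contains only positive members, with a
log accounting for every removal.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.8
REASON_CLUSTERED = "clustered-with-negative"
REASON_LOW_EXPRESSION = "low-expression"


@dataclass
class SignatureSet:
    """Ordered driver-correlated gene signature with provenance.

    ``members`` is indexed by gene id, ordered by descending r, with
    columns ``r`` and ``direction`` (+1 / -1).  ``refinement_log`` lists
    removed genes with their reason.
    """

    driver_gene: str
    members: pd.DataFrame
    cutoff: float
    refinement_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reason"])
    )

    def __post_init__(self) -> None:
        pos = self.members[self.members["direction"] > 0]
        neg = self.members[self.members["direction"] < 0]
        if (pos["r"] <= self.cutoff).any() or (neg["r"] >= -self.cutoff).any():
            raise ValueError("signature members violate the correlation cutoff")

    @property
    def positive_genes(self) -> list[str]:
        return list(self.members.index[self.members["direction"] > 0])

    @property
    def negative_genes(self) -> list[str]:
        return list(self.members.index[self.members["direction"] < 0])

    def __len__(self) -> int:
        return len(self.members)

    def to_gmt_sets(self, prefix: str = "signature") -> dict[str, list[str]]:
        return {
            f"{prefix}_positive": self.positive_genes,
            f"{prefix}_negative": self.negative_genes,
        }


def neighbor_correlations(
    matrix: ExpressionMatrix, driver_gene: str
) -> pd.Series:
    """Pearson r of every gene's profile with the driver's profile.

    The driver itself is excluded from the output, which is rank-ordered
    by descending r (ties broken by gene id).  Genes with zero variance
    across samples get r = 0.
    """
    if driver_gene not in matrix.values.index:
        raise KeyError(f"driver gene {driver_gene!r} not in matrix")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = matrix.values.to_numpy()
    driver = matrix.values.loc[driver_gene].to_numpy()
    d = driver - driver.mean()
    d_norm = math.sqrt((d**2).sum())
    if d_norm == 0:
        raise ValueError("driver profile has zero variance")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ d) / (norms * d_norm)
    r = np.where(norms == 0, 0.0, r)
    series = pd.Series(r, index=matrix.gene_ids).drop(driver_gene)
    order = sorted(series.index, key=lambda g: (-series[g], g))
    return series.loc[order]


def select_signature(
    correlations: pd.Series,
    driver_gene: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> SignatureSet:
    """Select genes beyond the +/- correlation cutoff (strict)."""
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    direction = pd.Series(0, index=correlations.index)
    direction[correlations > cutoff] = 1
    direction[correlations < -cutoff] = -1
    members = pd.DataFrame(
        {"r": correlations[direction != 0], "direction": direction[direction != 0]}
    )
    members = members.reindex(
        sorted(members.index, key=lambda g: (-members.loc[g, "r"], g))
    )
    if members.empty:
        warnings.warn("empty signature: no gene passes the correlation cutoff")
    logger.info(
        "signature at cutoff %.2f: %d positive, %d negative",
        cutoff, int((members["direction"] > 0).sum()), int((members["direction"] < 0).sum()),
    )
    return SignatureSet(driver_gene=driver_gene, members=members, cutoff=cutoff)


def _smallest_cluster_with(tree, leaf_names: list[str], wanted: set[str]):
    """Descend from the root to the smallest node containing all of ``wanted``."""
    node = tree
    while not node.is_leaf():
        left, right = node.get_left(), node.get_right()
        left_leaves = {leaf_names[i] for i in left.pre_order()}
        if wanted <= left_leaves:
            node = left
            continue
        right_leaves = {leaf_names[i] for i in right.pre_order()}
        if wanted <= right_leaves:
            node = right
            continue
        break
    return node


def refine_signature(
    matrix: ExpressionMatrix,
    signature: SignatureSet,
    control_samples: Sequence[str],
    expression_floor: float,
    linkage_method: str = "average",
) -> SignatureSet:
    """Refine the signature to a clean positively correlated gene set.

    Step (i): hierarchically cluster all signature genes on their
    profiles across the series (distance 1 - Pearson, ``linkage_method``
    linkage); positive genes falling inside the smallest cluster
    containing every negative gene are removed.  When the negatives only
    reunite at the root the step is skipped with a warning.  Step (ii):
    positive genes whose expression is below ``expression_floor`` in at
    least ceil(0.75 * n_controls) control samples are removed.  The
    result keeps only positive members.
    """
    control_samples = list(control_samples)
    if len(control_samples) < 2:
        raise ValueError("need at least 2 control samples")
    removed: list[tuple[str, str]] = []
    positives = signature.positive_genes
    negatives = signature.negative_genes

    # (i) genes co-clustering with the negative program
    if negatives and positives:
        genes = list(signature.members.index)
        profiles = matrix.values.loc[genes].to_numpy()
        corr = np.corrcoef(profiles)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        tree = to_tree(linkage(squareform(dist, checks=False), method=linkage_method))
        node = _smallest_cluster_with(tree, genes, set(negatives))
        cluster = {genes[i] for i in node.pre_order()}
        if cluster == set(genes):
            warnings.warn(
                "negative genes only co-cluster at the root; "
                "clustering-based removal skipped"
            )
            logger.info("refinement step (i) skipped: negatives split across the root")
        else:
            for g in positives:
                if g in cluster:
                    removed.append((g, REASON_CLUSTERED))

    # (ii) low expression in control samples
    surviving = [g for g in positives if (g, REASON_CLUSTERED) not in removed]
    n_required = math.ceil(0.75 * len(control_samples))
    low_counts = (matrix.values.loc[surviving, control_samples] < expression_floor).sum(axis=1)
    for g in surviving:
        if low_counts[g] >= n_required:
            removed.append((g, REASON_LOW_EXPRESSION))

    # the negative members themselves are dropped: the refined set is the
    # clean positive program, and the log must account for every removal
    for g in negatives:
        removed.append((g, REASON_CLUSTERED))

    removed_genes = {g for g, _ in removed}
    keep = [g for g in positives if g not in removed_genes]
    members = signature.members.loc[keep]
    log = pd.concat(
        [
            signature.refinement_log,
            pd.DataFrame(removed, columns=["gene", "reason"]),
        ],
        ignore_index=True,
    )
    logger.info(
        "refined signature: %d -> %d positives (%d clustered-with-negative, "
        "%d low-expression; %d negatives dropped)",
        len(positives), len(keep),
        sum(1 for _, r in removed if r == REASON_CLUSTERED),
        sum(1 for _, r in removed if r == REASON_LOW_EXPRESSION),
        len(negatives),
    )
    return SignatureSet(
        driver_gene=signature.driver_gene,
        members=members,
        cutoff=signature.cutoff,
        refinement_log=log,
    )
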