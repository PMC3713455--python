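"""Gene-level collapsing, expression filtering, relative-expression reports.

Probe-level matrices are collapsed to one row per gene (max-mean probe
representative), non-expressed genes are removed by a configurable floor
rule, and per-sample relative expression of a named gene is reported as
a percentage of a reference group's linear-scale mean — the quantity
used to call samples "driver-low" (e.g. at or below 45% of the normal
CD34+ mean).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_FLOOR_PERCENTILE = 20.0
DEFAULT_MIN_FRACTION = 0.25
DEFAULT_LOW_THRESHOLD_PERCENT = 45.0


def collapse_to_genes(
    probe_matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one canonical row per gene.

    For each gene the probe with the highest mean across samples is kept
    (ties broken by lexicographically smallest probe id).  Probes with
    no mapping are dropped and counted.
    """
    probes = probe_matrix.values.index
    mapped = [p for p in probes if p in probe_to_gene]
    unmapped = len(probes) - len(mapped)
    if not mapped:
        raise ValueError("probe-to-gene map covers zero probes")

    means = probe_matrix.values.mean(axis=1)
    # sort by (gene, -mean, probe id): the first probe per gene wins
    order = sorted(mapped, key=lambda p: (probe_to_gene[p], -means[p], p))
    chosen: dict[str, str] = {}
    for p in order:
        chosen.setdefault(probe_to_gene[p], p)

    genes = sorted(chosen)
    out = probe_matrix.values.loc[[chosen[g] for g in genes]]
    out.index = pd.Index(genes)
    logger.info(
        "collapsed %d probes to %d genes (%d unmapped probes dropped)",
        len(probes), len(genes), unmapped,
    )
    return ExpressionMatrix(out, probe_matrix.sample_annotations)


def filter_nonexpressed(
    matrix: ExpressionMatrix,
    floor: float | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ExpressionMatrix:
    """Remove genes not expressed above ``floor`` often enough.

    A gene is retained when its value exceeds ``floor`` in at least
    ``min_fraction`` of samples.  ``floor`` defaults to the 20th
    percentile of all matrix values.
    """
    if floor is None:
        floor = float(np.percentile(matrix.values.to_numpy(), DEFAULT_FLOOR_PERCENTILE))
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    expressed = (matrix.values > floor).mean(axis=1) >= min_fraction
    n_kept = int(expressed.sum())
    if n_kept == 0:
        raise ValueError(f"all genes removed at floor {floor:g}")
    logger.info(
        "expression filter (floor=%.4g, min_fraction=%.2f): kept %d, removed %d",
        floor, min_fraction, n_kept, matrix.n_genes - n_kept,
    )
    return ExpressionMatrix(
        matrix.values.loc[expressed], matrix.sample_annotations
    )


@dataclass
class RelativeExpressionReport:
    """Per-sample relative expression of one gene vs a reference group."""

    gene: str
    reference_group: str
    threshold_percent: float
    percent: pd.Series  # per sample, % of reference linear-scale mean
    low_flag: pd.Series  # percent <= threshold_percent

    @property
    def mean_of_low(self) -> float:
        """Mean percent over flagged samples (NaN when none are low)."""
        flagged = self.percent[self.low_flag]
        return float(flagged.mean()) if len(flagged) else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percent": self.percent, "low": self.low_flag})


def relative_expression(
    matrix: ExpressionMatrix,
    gene: str,
    reference_group: str,
    threshold_percent: float = DEFAULT_LOW_THRESHOLD_PERCENT,
) -> RelativeExpressionReport:
    """Express one gene per sample as % of a reference group's mean.

    The mean is taken on the linear scale (intensities, not log2), so a
    sample sitting 2 log2 units below the reference mean reports 25%.
    Samples at or below ``threshold_percent`` are flagged low.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    ref_samples = matrix.samples_in_group(reference_group)
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    linear = np.exp2(matrix.values.loc[gene])
    ref_mean = float(linear[ref_samples].mean())
    percent = 100.0 * linear / ref_mean
    low = percent <= threshold_percent
    return RelativeExpressionReport(
        gene=gene,
        reference_group=reference_group,
        threshold_percent=threshold_percent,
        percent=percent,
        low_flag=low,
    )
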