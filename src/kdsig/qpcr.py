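"""Efficiency-corrected relative quantification of qRT-PCR Ct data.

Per (sample, gene) the input quantity is Q = E^(-mean Ct), with E the
primer pair's mean amplification efficiency (fold amplification per
cycle) and the mean taken over replicate Ct values.  Each sample is
normalized by the geometric mean of its reference-gene quantities
(three housekeeping references by default, following the
PAPOLA / UBQLN1 / VPS39 convention), and each gene is then scaled so
that the control-sample mean equals 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import RelativeExpressionReport

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_GENES = ("PAPOLA", "UBQLN1", "VPS39")


@dataclass
class CtTable:
    """Long-format Ct records with per-primer efficiencies.

    ``records`` has columns ``sample``, ``gene``, ``replicate``, ``ct``;
    undetermined (no-amplification) wells are encoded as NaN, never as a
    sentinel cycle number.  Triplicates are expected; missing replicates
    are tolerated and logged.
    """

    records: pd.DataFrame
    efficiencies: dict[str, float]
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES
    control_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"Ct records missing columns: {sorted(missing)}")
        for g in self.records["gene"].unique():
            if g not in self.efficiencies:
                raise ValueError(f"no amplification efficiency for gene {g!r}")
        for g, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise ValueError(f"efficiency for {g!r} must lie in (1, 2.2], got {e}")
        if not self.control_samples:
            raise ValueError("at least one control sample is required")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct, samples x genes (NaN where absent)."""
        counts = self.records.dropna(subset=["ct"]).groupby(["sample", "gene"]).size()
        short = counts[counts < 3]
        if len(short):
            logger.info("%d (sample, gene) pairs have fewer than 3 replicates", len(short))
        return self.records.pivot_table(
            index="sample", columns="gene", values="ct", aggfunc="mean"
        )


@dataclass
class RelativeQuantity:
    """Normalized relative expression, control mean scaled to 1."""

    values: pd.DataFrame  # samples x genes
    flagged_samples: list[str] = field(default_factory=list)

    def gene(self, gene: str) -> pd.Series:
        return self.values[gene]


def quantify(ct: CtTable) -> RelativeQuantity:
    """Efficiency-corrected, reference-normalized, control-scaled quantities.

    Steps: (1) Q = E^(-mean Ct) per (sample, gene); (2) divide each
    sample by the geometric mean of its reference-gene quantities;
    (3) divide each gene by the mean of its normalized values over the
    control samples.  A sample missing one or more reference genes is
    flagged and excluded from the control-scaling denominator; its
    normalization uses the references it does have (none at all leaves
    the sample NaN).
    """
    mean_ct = ct.mean_ct()
    missing_refs = [g for g in ct.reference_genes if g not in mean_ct.columns]
    if missing_refs:
        raise ValueError(f"reference genes absent from the table: {missing_refs}")
    eff = pd.Series({g: ct.efficiencies[g] for g in mean_ct.columns})
    q = eff.to_numpy() ** (-mean_ct)

    ref_q = q[list(ct.reference_genes)]
    flagged = list(ref_q.index[ref_q.isna().any(axis=1)])
    if flagged:
        logger.info("samples with missing reference measurements: %s", flagged)
    # geometric mean of available references per sample
    factor = np.exp(np.log(ref_q).mean(axis=1, skipna=True))
    normalized = q.div(factor, axis=0)

    controls = [s for s in ct.control_samples if s in normalized.index]
    if not controls:
        raise ValueError("no control sample present in the Ct table")
    scaling_controls = [s for s in controls if s not in flagged]
    if not scaling_controls:
        raise ValueError("all control samples are flagged (missing references)")
    control_mean = normalized.loc[scaling_controls].mean(axis=0, skipna=True)
    scaled = normalized.div(control_mean, axis=1)
    return RelativeQuantity(values=scaled, flagged_samples=flagged)


def correlate_with_array(
    qpcr_values: pd.Series,
    array_report: RelativeExpressionReport,
) -> float:
    """Pearson r between qPCR and microarray relative expression.

    Computed over the samples shared by the two measurements (at
    least 3 required).
    """
    shared = qpcr_values.index.intersection(array_report.percent.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    r, _ = stats.pearsonr(
        qpcr_values[shared].to_numpy(dtype=float),
        array_report.percent[shared].to_numpy(dtype=float),
    )
    return float(r)
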