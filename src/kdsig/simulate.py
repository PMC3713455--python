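"""Synthetic data with the statistical structure the pipeline assumes.

Three generators cover the three kinds of input the analysis consumes:

* a knockdown series — one unperturbed sample, a handful of
  control-shRNA samples, and a ladder of driver-specific shRNA samples
  whose residual driver expression spans roughly 5-30% of the control
  level, with planted positively- and negatively-coupled target genes;
* a patient cohort in which "driver-low" cases carry the planted
  signature shifted down according to a per-case residual fraction
  (default 20-45% of normal), optionally passed through a per-gene
  affine platform distortion with gene dropout;
* a qPCR plate of triplicate Ct values with known per-primer
  amplification efficiencies and planted relative quantities.

Every generator emits a truth object sufficient to score the downstream
stage (signature recovery, label recovery, quantity recovery) without
inspecting internal state.  All randomness flows from the design's seed
through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    GROUP_CONTROL_SHRNA,
    GROUP_DRIVER_SHRNA,
    GROUP_MDS,
    GROUP_NORMAL,
    GROUP_UNPERTURBED,
    ExpressionMatrix,
)

DRIVER_GENE = "DRIVER"

# per-gene baseline log2 intensities: lognormal-in-linear microarray model
BASELINE_MEAN = 7.0
BASELINE_SD = 2.0
# the driver is a solidly expressed gene in unperturbed cells; a fixed
# baseline keeps it clear of any sensible expression floor
DRIVER_BASELINE = 9.0


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


# ======================================================================
# knockdown series
@dataclass(frozen=True)
class KnockdownDesign:
    """Design of the shRNA knockdown series.

    ``residual_fractions`` gives, per driver-shRNA sample, the residual
    driver expression as a fraction of the control-group mean on the
    linear scale.  The default ladder spans 5-30% in eight steps, the
    gradient over which a graded-potency hairpin series operates.
    ``coupling_slopes`` is the log2 change of each planted target per
    unit log2 change of the driver (scalar broadcast to all targets).
    """

    n_genes: int = 2000
    n_target_pos: int = 80
    n_target_neg: int = 10
    residual_fractions: tuple[float, ...] = tuple(
        round(f, 6) for f in np.linspace(0.05, 0.30, 8)
    )
    n_control_samples: int = 4
    n_unperturbed: int = 1
    noise_sd: float = 0.3
    coupling_slopes: float | tuple[float, ...] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd",):
            _check_finite(name, getattr(self, name))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_target_pos + self.n_target_neg >= self.n_genes:
            raise ValueError("planted targets must number fewer than n_genes")
        if not self.residual_fractions:
            raise ValueError("need at least one driver-shRNA sample")
        for f in self.residual_fractions:
            _check_finite("residual_fraction", f)
            if not (0 < f <= 1):
                raise ValueError(f"residual fractions must lie in (0, 1], got {f}")
        slopes = np.atleast_1d(np.asarray(self.coupling_slopes, dtype=float))
        if not np.isfinite(slopes).all():
            raise ValueError("coupling_slopes must be finite")
        if slopes.size not in (1, self.n_target_pos + self.n_target_neg):
            raise ValueError(
                "coupling_slopes must be scalar or one per planted target"
            )

    @property
    def n_samples(self) -> int:
        return self.n_unperturbed + self.n_control_samples + len(self.residual_fractions)

    def slopes(self) -> np.ndarray:
        """Per-target |slope|, positives first then negatives."""
        n_targets = self.n_target_pos + self.n_target_neg
        slopes = np.atleast_1d(np.asarray(self.coupling_slopes, dtype=float))
        if slopes.size == 1:
            slopes = np.full(n_targets, float(slopes[0]))
        return slopes


def simulate_knockdown_series(
    design: KnockdownDesign,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the knockdown series.

    Returns the expression matrix and a truth table indexed by gene id
    with columns ``role`` (driver / target_pos / target_neg / null) and
    ``slope`` (signed coupling slope; NaN for null genes).
    """
    rng = np.random.default_rng(design.seed)
    n_kd = len(design.residual_fractions)
    n_ctrl = design.n_unperturbed + design.n_control_samples

    # gene universe: driver, planted targets, null genes
    pos_ids = [f"POS{i + 1:04d}" for i in range(design.n_target_pos)]
    neg_ids = [f"NEG{i + 1:04d}" for i in range(design.n_target_neg)]
    n_null = design.n_genes - 1 - design.n_target_pos - design.n_target_neg
    null_ids = [f"G{i + 1:05d}" for i in range(n_null)]
    gene_ids = [DRIVER_GENE] + pos_ids + neg_ids + null_ids

    sample_ids = (
        [f"UNPERT{i + 1}" for i in range(design.n_unperturbed)]
        + [f"CTRL{i + 1}" for i in range(design.n_control_samples)]
        + [f"KD{i + 1}" for i in range(n_kd)]
    )
    groups = (
        [GROUP_UNPERTURBED] * design.n_unperturbed
        + [GROUP_CONTROL_SHRNA] * design.n_control_samples
        + [GROUP_DRIVER_SHRNA] * n_kd
    )
    shrna = (
        [pd.NA] * design.n_unperturbed
        + [f"ctrl-{chr(ord('A') + i)}" for i in range(design.n_control_samples)]
        + [f"sh{i + 1}" for i in range(n_kd)]
    )

    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=design.n_genes)
    baselines[0] = DRIVER_BASELINE

    # driver log2 deviation from its control-mean baseline, noise-free
    signal = np.concatenate([np.zeros(n_ctrl), np.log2(design.residual_fractions)])

    values = np.empty((design.n_genes, design.n_samples))
    values[0] = baselines[0] + signal
    abs_slopes = design.slopes()
    signs = np.concatenate(
        [np.ones(design.n_target_pos), -np.ones(design.n_target_neg)]
    )
    slopes = signs * abs_slopes
    n_targets = len(slopes)
    values[1 : 1 + n_targets] = (
        baselines[1 : 1 + n_targets, None] + slopes[:, None] * signal[None, :]
    )
    values[1 + n_targets :] = baselines[1 + n_targets :, None]
    values += rng.normal(0.0, design.noise_sd, size=values.shape)

    annotations = pd.DataFrame(
        {
            "group": groups,
            "cohort": "knockdown-series",
            "shrna": shrna,
            "residual_fraction": [np.nan] * n_ctrl + list(design.residual_fractions),
        },
        index=sample_ids,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), annotations
    )
    truth = pd.DataFrame(
        {
            "role": ["driver"]
            + ["target_pos"] * design.n_target_pos
            + ["target_neg"] * design.n_target_neg
            + ["null"] * n_null,
            "slope": [1.0] + list(slopes) + [np.nan] * n_null,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return matrix, truth


# ======================================================================
# patient cohort
@dataclass(frozen=True)
class PlatformDistortion:
    """Per-gene affine distortion plus gene dropout.

    Models cross-platform inconsistency: each gene's log2 profile is
    mapped through ``scale * x + offset`` with gene-specific parameters,
    and a fraction of genes is absent from the test platform entirely.
    """

    scale_sd: float = 0.1
    offset_sd: float = 0.5
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.scale_sd < 0 or self.offset_sd < 0:
            raise ValueError("distortion SDs must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Design of a patient cohort with planted driver-low cases.

    ``signature_genes`` maps gene id to direction (+1 for genes that
    track the driver, -1 for anti-correlated genes); driver-low cases
    have each signature gene shifted by ``direction * log2(f)`` with the
    per-case residual fraction ``f`` drawn uniformly from
    ``case_driver_fraction_range``.  The driver itself shifts by
    ``log2(f)``.
    """

    signature_genes: Mapping[str, int]
    n_cases_low: int = 17
    n_cases_normal: int = 9
    n_controls: int = 4
    case_driver_fraction_range: tuple[float, float] = (0.20, 0.45)
    noise_sd: float = 0.5
    n_genes: int = 2000
    platform_distortion: PlatformDistortion | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise ValueError("signature_genes must be nonempty")
        lo, hi = self.case_driver_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("case_driver_fraction_range must lie within (0, 1)")
        _check_finite("noise_sd", self.noise_sd)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g, d in self.signature_genes.items():
            if d not in (-1, 1):
                raise ValueError(f"direction for {g} must be +1 or -1, got {d}")


@dataclass
class CohortTruth:
    """Ground truth emitted alongside a simulated cohort."""

    labels: pd.DataFrame  # index sample; columns: label, driver_fraction
    dropped_genes: list[str] = field(default_factory=list)


def simulate_patient_cohort(
    design: CohortDesign,
    gene_ids: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a patient cohort carrying the planted signature.

    ``gene_ids`` fixes the gene universe (so cohort and knockdown series
    share identifiers); by default the driver plus the signature genes
    are embedded in ``n_genes`` total genes named as in the knockdown
    generator.
    """
    rng = np.random.default_rng(design.seed)
    if gene_ids is None:
        sig = list(design.signature_genes)
        n_null = design.n_genes - 1 - len(sig)
        if n_null < 0:
            raise ValueError("n_genes too small for the signature")
        gene_ids = [DRIVER_GENE] + sig + [f"G{i + 1:05d}" for i in range(n_null)]
    gene_ids = list(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in design.signature_genes if g not in gene_pos]
    if missing:
        raise ValueError(f"signature genes absent from gene universe: {missing[:5]}")
    if DRIVER_GENE not in gene_pos:
        raise ValueError("gene universe must include the driver gene")

    n_cases = design.n_cases_low + design.n_cases_normal
    sample_ids = [f"MDS{i + 1:02d}" for i in range(n_cases)] + [
        f"NBM{i + 1:02d}" for i in range(design.n_controls)
    ]
    labels = (
        ["driver-low"] * design.n_cases_low
        + ["normal-like"] * design.n_cases_normal
        + ["control"] * design.n_controls
    )
    groups = [GROUP_MDS] * n_cases + [GROUP_NORMAL] * design.n_controls

    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(gene_ids))
    baselines[gene_pos[DRIVER_GENE]] = DRIVER_BASELINE
    values = np.tile(baselines[:, None], (1, len(sample_ids)))

    lo, hi = design.case_driver_fraction_range
    fractions = rng.uniform(lo, hi, size=design.n_cases_low)
    for j, f in enumerate(fractions):
        shift = math.log2(f)
        values[gene_pos[DRIVER_GENE], j] += shift
        for g, direction in design.signature_genes.items():
            values[gene_pos[g], j] += direction * shift

    values += rng.normal(0.0, design.noise_sd, size=values.shape)

    dropped: list[str] = []
    keep = np.ones(len(gene_ids), dtype=bool)
    if design.platform_distortion is not None:
        dist = design.platform_distortion
        scale = rng.normal(1.0, dist.scale_sd, size=len(gene_ids))
        offset = rng.normal(0.0, dist.offset_sd, size=len(gene_ids))
        values = scale[:, None] * values + offset[:, None]
        if dist.dropout > 0:
            keep = rng.random(len(gene_ids)) >= dist.dropout
            if not keep.any():
                keep[0] = True
            dropped = [g for g, k in zip(gene_ids, keep) if not k]

    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids).loc[keep]
    annotations = pd.DataFrame(
        {
            "group": groups,
            "cohort": "patient-cohort",
            "karyotype": ["normal"] * len(sample_ids),
        },
        index=sample_ids,
    )
    truth = CohortTruth(
        labels=pd.DataFrame(
            {
                "label": labels,
                "driver_fraction": list(fractions)
                + [np.nan] * (design.n_cases_normal + design.n_controls),
            },
            index=pd.Index(sample_ids, name="sample"),
        ),
        dropped_genes=dropped,
    )
    return ExpressionMatrix(frame, annotations), truth


# ======================================================================
# qPCR plate
def simulate_qpcr_plate(
    true_quantities: pd.DataFrame,
    efficiencies: Mapping[str, float],
    reference_genes: Sequence[str],
    control_samples: Sequence[str],
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Simulate triplicate Ct measurements for known relative quantities.

    ``true_quantities`` is samples x genes on the linear scale (positive).
    Ct for a well is ``baseline_g - log_E(quantity) + noise`` where the
    per-gene baseline Ct is drawn once and the amplification efficiency
    ``E`` is the fold amplification per cycle for that primer pair.
    Returns a :class:`kdsig.qpcr.CtTable`.
    """
    from .qpcr import CtTable  # deferred to avoid an import cycle

    rng = np.random.default_rng(seed)
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    q = true_quantities.to_numpy(dtype=float)
    if not (q > 0).all():
        raise ValueError("true relative quantities must be positive")
    genes = list(true_quantities.columns)
    for g in genes:
        if g not in efficiencies:
            raise ValueError(f"no efficiency for gene {g}")
        e = efficiencies[g]
        if not (1.6 <= e <= 2.1):
            raise ValueError(f"efficiency for {g} must lie in [1.6, 2.1], got {e}")

    baseline_ct = {g: rng.uniform(20.0, 28.0) for g in genes}
    records = []
    for sample, row in true_quantities.iterrows():
        for g in genes:
            e = efficiencies[g]
            ideal = baseline_ct[g] - math.log(row[g], e)
            for rep in range(1, n_replicates + 1):
                ct = ideal + rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else ideal
                records.append((sample, g, rep, ct))
    table = pd.DataFrame(records, columns=["sample", "gene", "replicate", "ct"])
    return CtTable(
        records=table,
        efficiencies=dict(efficiencies),
        reference_genes=tuple(reference_genes),
        control_samples=tuple(control_samples),
    )
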