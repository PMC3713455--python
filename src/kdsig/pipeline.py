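"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` drives simulate -> preprocess -> marker selection ->
signature derivation -> enrichment -> classification -> relative
expression, writing each stage's result as a serialized artifact (GCT,
TSV, GMT, JSON) plus a line-structured run log and the fully resolved
configuration.  Stages communicate only through those artifacts, the
global seed is split deterministically per stage, and an identical
configuration and seed reproduce the bundle byte-for-byte (the run log
carries wall-clock timestamps and is the one exception).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, knn, markers, preprocess, signature, simulate
from .io import FLOAT_FORMAT, write_cls, write_gct, write_gmt
from .matrix import GROUP_MDS, GROUP_NORMAL

logger = logging.getLogger(__name__)

N_STAGE_SEEDS = 8


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters with defaults mirroring the study design."""

    seed: int = 0
    outdir: str = "kdsig-run"

    # synthetic inputs
    knockdown: dict = field(default_factory=dict)  # KnockdownDesign overrides
    cohort: dict = field(default_factory=dict)  # CohortDesign overrides

    # preprocessing
    filter_floor: float | None = None  # default: 20th percentile
    filter_min_fraction: float = preprocess.DEFAULT_MIN_FRACTION
    low_threshold_percent: float = preprocess.DEFAULT_LOW_THRESHOLD_PERCENT

    # marker selection
    q_max: float = markers.DEFAULT_Q_MAX
    fc_min: float = markers.DEFAULT_FC_MIN
    de_n_perm: int = markers.DEFAULT_N_PERM

    # signature
    cutoff: float = signature.DEFAULT_CUTOFF
    linkage_method: str = "average"
    expression_floor: float | None = None  # default: 20th percentile of series

    # enrichment
    gsea_n_perm: int = 999
    gsea_weight: float = enrichment.DEFAULT_WEIGHT
    gsea_mode: str = "phenotype"

    # classification
    k: int = knn.DEFAULT_K

    # stage toggles
    run_de: bool = True
    run_signature: bool = True
    run_gsea: bool = True
    run_classify: bool = True
    run_relative_expression: bool = True

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check every stage's parameters before any stage runs."""
        if self.k % 2 == 0:
            raise ValueError(
                f"k={self.k} is even: an even neighbor count can deadlock the "
                "majority vote; choose an odd k"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.cutoff < 1):
            raise ValueError("correlation cutoff must lie in (0, 1)")
        if not (0 < self.q_max <= 1):
            raise ValueError("q_max must lie in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.de_n_perm < 100 or self.gsea_n_perm < 100:
            raise ValueError("permutation counts must be >= 100")
        if self.gsea_mode not in ("phenotype", "gene-set"):
            raise ValueError(f"unknown gsea_mode {self.gsea_mode!r}")
        if not (0 < self.filter_min_fraction <= 1):
            raise ValueError("filter_min_fraction must lie in (0, 1]")
        # construct the designs so their own invariants run too
        self._designs_check()

    def _designs_check(self) -> None:
        simulate.KnockdownDesign(**{**self.knockdown, "seed": 0})
        cohort = dict(self.cohort)
        cohort.pop("seed", None)
        simulate.CohortDesign(signature_genes={"POS0001": 1}, **cohort, seed=0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _stage_seeds(seed: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(N_STAGE_SEEDS)]


class _RunLog:
    """Line-structured log: timestamp <tab> stage <tab> event <tab> detail."""

    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def write(self, stage: str, event: str, detail: str = "") -> None:
        ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
        with self.path.open("a") as fh:
            fh.write(f"{ts}\t{stage}\t{event}\t{detail}\n")
        logger.info("[%s] %s %s", stage, event, detail)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the synthetic end-to-end analysis; return the output bundle.

    On any stage failure all files written so far are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    written: dict[str, Path] = {}
    log = _RunLog(outdir / "run.log")
    written["run_log"] = outdir / "run.log"

    config.to_yaml(outdir / "effective_config.yaml")
    written["effective_config"] = outdir / "effective_config.yaml"

    stage = "simulate"
    try:
        # ---------------------------------------------------------- simulate
        kd_design = simulate.KnockdownDesign(**{**config.knockdown, "seed": seeds[0]})
        series, kd_truth = simulate.simulate_knockdown_series(kd_design)
        planted = {
            g: (1 if role == "target_pos" else -1)
            for g, role in kd_truth["role"].items()
            if role in ("target_pos", "target_neg")
        }
        cohort_over = dict(config.cohort)
        cohort_over.pop("seed", None)
        cohort_design = simulate.CohortDesign(
            signature_genes=planted, **cohort_over, seed=seeds[1]
        )
        cohort, cohort_truth = simulate.simulate_patient_cohort(
            cohort_design, gene_ids=list(series.gene_ids)
        )
        write_gct(series, outdir / "series.gct")
        write_gct(cohort, outdir / "cohort.gct")
        kd_truth.to_csv(outdir / "series_truth.tsv", sep="\t")
        cohort_truth.labels.to_csv(
            outdir / "cohort_truth.tsv", sep="\t", float_format=FLOAT_FORMAT
        )
        write_cls(list(cohort.groups), outdir / "cohort.cls")
        written.update(
            series=outdir / "series.gct",
            cohort=outdir / "cohort.gct",
            series_truth=outdir / "series_truth.tsv",
            cohort_truth=outdir / "cohort_truth.tsv",
            cohort_cls=outdir / "cohort.cls",
        )
        log.write(stage, "done", f"series {series.n_samples} samples, "
                  f"cohort {cohort.n_samples} samples, {series.n_genes} genes")

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        filtered = preprocess.filter_nonexpressed(
            series, floor=config.filter_floor, min_fraction=config.filter_min_fraction
        )
        if simulate.DRIVER_GENE not in filtered.values.index:
            # the driver anchors the whole analysis; keep it regardless
            kept = pd.concat(
                [series.values.loc[[simulate.DRIVER_GENE]], filtered.values]
            )
            filtered = type(filtered)(kept, series.sample_annotations)
            log.write(stage, "note", "driver re-inserted after expression filter")
        log.write(stage, "done", f"series genes {series.n_genes} -> {filtered.n_genes}")

        # --------------------------------------------------------- signature
        refined = None
        if config.run_signature:
            stage = "signature"
            corr = signature.neighbor_correlations(filtered, simulate.DRIVER_GENE)
            sig = signature.select_signature(corr, simulate.DRIVER_GENE, config.cutoff)
            floor = config.expression_floor
            if floor is None:
                floor = float(
                    np.percentile(series.values.to_numpy(), preprocess.DEFAULT_FLOOR_PERCENTILE)
                )
            controls = series.samples_in_group("control-shRNA") + series.samples_in_group(
                "unperturbed"
            )
            refined = signature.refine_signature(
                filtered, sig, controls, floor, config.linkage_method
            )
            write_gmt(refined.to_gmt_sets(), outdir / "signature.gmt")
            sig.members.to_csv(
                outdir / "signature.tsv", sep="\t", float_format=FLOAT_FORMAT
            )
            refined.refinement_log.to_csv(
                outdir / "refinement_log.tsv", sep="\t", index=False
            )
            written.update(
                signature_gmt=outdir / "signature.gmt",
                signature_tsv=outdir / "signature.tsv",
                refinement_log=outdir / "refinement_log.tsv",
            )
            log.write(stage, "done",
                      f"{len(sig.positive_genes)}+/{len(sig.negative_genes)}- -> "
                      f"{len(refined.positive_genes)} refined")

        # ---------------------------------------------------------------- de
        cohort_labels = cohort.groups
        if config.run_de:
            stage = "differential-expression"
            de = markers.marker_scores(
                cohort, cohort_labels, n_perm=config.de_n_perm, seed=seeds[2]
            )
            selected = markers.select_differential(de, config.q_max, config.fc_min)
            de.loc[selected].to_csv(
                outdir / "de_markers.tsv", sep="\t", float_format=FLOAT_FORMAT
            )
            written["de_markers"] = outdir / "de_markers.tsv"
            log.write(stage, "done", f"{len(selected)} genes at "
                      f"q<={config.q_max} fc>={config.fc_min}")

        # -------------------------------------------------------------- gsea
        if config.run_gsea and refined is not None:
            stage = "gsea"
            res = enrichment.gsea_significance(
                cohort,
                cohort_labels,
                refined.positive_genes,
                n_perm=config.gsea_n_perm,
                permutation_mode=config.gsea_mode,
                seed=seeds[3],
                weight_exponent=config.gsea_weight,
            )
            (outdir / "enrichment.json").write_text(
                json.dumps(res.to_dict(), indent=2) + "\n"
            )
            written["enrichment"] = outdir / "enrichment.json"
            log.write(stage, "done", f"ES={res.es:.3f} p={res.p_perm:.4g}")

        # ---------------------------------------------------------- classify
        if config.run_classify and refined is not None:
            stage = "classify"
            training = knn.build_training_set(series, refined)
            result = knn.knn_classify(training, cohort, k=config.k)
            result.to_frame().to_csv(
                outdir / "classification.tsv", sep="\t", float_format=FLOAT_FORMAT
            )
            written["classification"] = outdir / "classification.tsv"
            n_low = int((result.predictions["label"] == knn.LABEL_DRIVER_LOW).sum())
            log.write(stage, "done",
                      f"{n_low}/{len(result.predictions)} classified driver-low")

        # ------------------------------------------------- relative expression
        if config.run_relative_expression:
            stage = "relative-expression"
            report = preprocess.relative_expression(
                cohort,
                simulate.DRIVER_GENE,
                GROUP_NORMAL,
                threshold_percent=config.low_threshold_percent,
            )
            report.to_frame().to_csv(
                outdir / "relative_expression.tsv", sep="\t", float_format=FLOAT_FORMAT
            )
            written["relative_expression"] = outdir / "relative_expression.tsv"
            log.write(stage, "done",
                      f"{int(report.low_flag.sum())} samples low; "
                      f"mean_of_low={report.mean_of_low:.1f}%")
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return written
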