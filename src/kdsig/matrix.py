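"""Gene-by-sample expression matrix with sample annotations.

The matrix is the universal substrate of the pipeline: log2-scale
intensities with genes on the rows and samples on the columns, plus a
sample-annotation table carrying group labels (``normal``, ``MDS``,
``control-shRNA``, ``driver-shRNA``), cohort, karyotype, shRNA id and
fluorophore where known.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# canonical group labels used throughout the pipeline
GROUP_NORMAL = "normal"
GROUP_MDS = "MDS"
GROUP_CONTROL_SHRNA = "control-shRNA"
GROUP_DRIVER_SHRNA = "driver-shRNA"
GROUP_UNPERTURBED = "unperturbed"

ANNOTATION_COLUMNS = ("group", "cohort", "karyotype", "shrna", "fluorophore")


class ExpressionMatrix:
    """Log2-scale expression values (genes x samples) with annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        All values must be finite; gene and sample ids must be unique.
    sample_annotations
        Optional DataFrame indexed by sample id.  Missing fields are
        allowed; missing samples are filled with NA rows.  Columns other
        than the canonical annotation columns are preserved.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_annotations: pd.DataFrame | None = None,
    ) -> None:
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        self.values = values.astype(float)

        if sample_annotations is None:
            sample_annotations = pd.DataFrame(index=self.values.columns)
        else:
            sample_annotations = sample_annotations.copy()
            extra = sample_annotations.index.difference(self.values.columns)
            if len(extra):
                raise ValueError(f"annotations for unknown samples: {list(extra)[:5]}")
            sample_annotations = sample_annotations.reindex(self.values.columns)
        for col in ANNOTATION_COLUMNS:
            if col not in sample_annotations.columns:
                sample_annotations[col] = pd.NA
        self.sample_annotations = sample_annotations

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> pd.Series:
        """Group label per sample (may contain NA)."""
        return self.sample_annotations["group"]

    # ------------------------------------------------------------------
    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {list(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[genes], self.sample_annotations)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {list(missing)[:5]}")
        return ExpressionMatrix(
            self.values.loc[:, samples], self.sample_annotations.loc[samples]
        )

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.groups == group
        return list(self.sample_ids[mask.to_numpy(dtype=bool)])

    def require_group_labels(self) -> None:
        """Raise unless every sample carries a group label."""
        missing = self.groups.isna()
        if missing.any():
            bad = list(self.sample_ids[missing.to_numpy()])
            raise ValueError(f"samples without a group label: {bad[:5]}")

    # ------------------------------------------------------------------
    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_annotations.copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.sample_annotations.equals(
            other.sample_annotations
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"
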