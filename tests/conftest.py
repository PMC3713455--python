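import numpy as np
import pandas as pd
import pytest

import kdsig
from kdsig.simulate import DRIVER_GENE


def make_matrix(values, genes=None, samples=None, groups=None):
    """Small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    ann = None
    if groups is not None:
        ann = pd.DataFrame({"group": list(groups)}, index=samples)
    return kdsig.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), ann
    )


@pytest.fixture(scope="session")
def kd_series():
    """Default knockdown series with its planted truth (seed 1)."""
    return kdsig.simulate_knockdown_series(kdsig.KnockdownDesign(seed=1))


@pytest.fixture(scope="session")
def noise_free_series():
    design = kdsig.KnockdownDesign(noise_sd=0.0, seed=1)
    return kdsig.simulate_knockdown_series(design), design


@pytest.fixture(scope="session")
def planted_signature(kd_series):
    """Gene -> direction map of the planted targets."""
    _, truth = kd_series
    return {
        g: (1 if role == "target_pos" else -1)
        for g, role in truth["role"].items()
        if role.startswith("target")
    }


@pytest.fixture(scope="session")
def default_cohort(kd_series, planted_signature):
    series, _ = kd_series
    design = kdsig.CohortDesign(signature_genes=planted_signature, seed=7)
    return kdsig.simulate_patient_cohort(design, gene_ids=list(series.gene_ids))


@pytest.fixture(scope="session")
def refined_signature(kd_series):
    series, _ = kd_series
    corr = kdsig.neighbor_correlations(series, DRIVER_GENE)
    sig = kdsig.select_signature(corr, DRIVER_GENE, 0.8)
    floor = float(np.percentile(series.values.to_numpy(), 20))
    controls = series.samples_in_group("control-shRNA") + series.samples_in_group(
        "unperturbed"
    )
    return kdsig.refine_signature(series, sig, controls, floor)
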