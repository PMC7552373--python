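import warnings

import numpy as np
import pandas as pd
import pytest

from lungsig import SimulationConfig, simulate_cohorts
from lungsig.containers import ExpressionMatrix
from lungsig.pipeline import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore", category=FutureWarning)


def make_matrix(values, genes=None, samples=None, phenotypes=None, study="s1"):
    """Small ExpressionMatrix from a 2-D array for unit tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"x{j}" for j in range(values.shape[1])]
    phenotypes = phenotypes or ["healthy"] * values.shape[1]
    sheet = pd.DataFrame(
        {"study_id": study, "phenotype": phenotypes},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), sheet)


def two_group_matrix(rng, n_disease, n_control, n_genes, effect_genes=None,
                     effect=0.0, noise_sd=0.5, disease="IPF"):
    """Disease-vs-healthy matrix with an optional planted shift."""
    base = rng.normal(8.0, 1.0, n_genes)
    vals = base[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_disease + n_control))
    if effect_genes:
        for g in effect_genes:
            vals[g, :n_disease] += effect
    phen = [disease] * n_disease + ["healthy"] * n_control
    return make_matrix(vals, phenotypes=phen)


@pytest.fixture(scope="session")
def default_cohort():
    """Default two-study synthetic cohorts plus ground truth (seed 1)."""
    config = SimulationConfig(seed=1)
    studies, sheet, truth = simulate_cohorts(config)
    return config, studies, sheet, truth


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """One full pipeline run on the default synthetic cohorts."""
    config, studies, sheet, truth = default_cohort
    report = run_pipeline(PipelineConfig(simulation=config, seed=1))
    return report, truth
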