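import numpy as np
import pandas as pd
import pytest

from albumin_mr import SimulationConfig, generate_cohort
from albumin_mr.cohort_core import VISIT_COLUMNS


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_subjects=400, n_null_snps=30, seed=20210528)


@pytest.fixture(scope="session")
def small_cohort(small_config, tmp_path_factory):
    """One generated cohort, written to disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    phenotype, genotypes, truth = generate_cohort(small_config, out)
    return {
        "dir": out,
        "phenotype": phenotype,
        "genotypes": genotypes,
        "truth": truth,
        "config": small_config,
    }


@pytest.fixture()
def baseline_visits(small_cohort):
    ph = small_cohort["phenotype"]
    baseline = ph[ph["visit_month"] == 0].drop(columns=["visit_month"])
    visits = ph[VISIT_COLUMNS]
    return baseline.reset_index(drop=True), visits.reset_index(drop=True)


def make_visits(rows):
    """rows: list of (month, sbp, dbp, med) for a single subject."""
    return pd.DataFrame(
        {
            "subject_id": ["s1"] * len(rows),
            "visit_month": [r[0] for r in rows],
            "sbp": [r[1] for r in rows],
            "dbp": [r[2] for r in rows],
            "med_flag": [int(r[3]) for r in rows],
        }
    )
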