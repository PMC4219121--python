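import numpy as np
import pandas as pd
import pytest

from survpool.cohorts import CLINICAL_COLUMNS, Cohort, assemble_compendium
from survpool.simulate import SimConfig, simulate_compendium


def make_clinical(sample_ids, **columns) -> pd.DataFrame:
    """Canonical clinical frame with NaN defaults; columns given as arrays."""
    clin = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for col in CLINICAL_COLUMNS[1:]:
        clin[col] = columns.get(col, np.nan)
    for col in ("os_time", "os_event", "dfs_time", "dfs_event", "age", "figo_stage", "grade"):
        clin[col] = pd.to_numeric(clin[col])
    return clin


def make_cohort(dataset_id, expr_rows: dict, clinical: pd.DataFrame | None = None,
                platform="test-chip") -> Cohort:
    """Cohort from a {gene: values} dict; clinical defaults to all-event OS
    times 1..n months."""
    expr = pd.DataFrame(expr_rows).T
    n = expr.shape[1]
    expr.columns = [f"{dataset_id}_s{j + 1}" for j in range(n)]
    expr.index = expr.index.astype(str)
    if clinical is None:
        clinical = make_clinical(
            expr.columns, os_time=np.arange(1.0, n + 1.0), os_event=np.ones(n)
        )
    else:
        clinical = clinical.set_axis(expr.columns, axis=0)
    return Cohort(dataset_id=dataset_id, platform=platform, expression=expr, clinical=clinical)


@pytest.fixture(scope="session")
def planted_compendium():
    """Small seeded compendium with one strongly planted deleterious gene."""
    cfg = SimConfig(
        seed=7,
        n_datasets=3,
        samples_per_dataset=80,
        n_genes=15,
        planted_effects={"10004": np.log(2.5)},
        endpoint_pattern="both",
    )
    comp, truth = simulate_compendium(cfg)
    return comp, truth, cfg


@pytest.fixture()
def two_cohort_compendium():
    rng = np.random.default_rng(11)
    cohorts = []
    for d in range(2):
        n = 40
        expr = {g: rng.normal(5 + d, 1 + d, n) for g in ("101", "102", "103")}
        clin = make_clinical(
            [f"s{j}" for j in range(n)],
            os_time=np.round(rng.exponential(30, n), 2) + 0.01,
            os_event=rng.integers(0, 2, n).astype(float),
        )
        cohorts.append(make_cohort(f"d{d + 1}", expr, clin))
    return assemble_compendium(cohorts)


def random_survival(rng, n, mean=20.0, censoring=0.4):
    """Random censored survival data for oracle comparisons."""
    t_event = rng.exponential(mean, n)
    t_cens = rng.exponential(mean * (1 - censoring) / max(censoring, 1e-9), n)
    time = np.round(np.minimum(t_event, t_cens), 1) + 0.1
    event = (t_event <= t_cens).astype(int)
    return time, event
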