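import numpy as np
import pandas as pd
import pytest

from irimap import (
    SimParams,
    build_irim,
    cosine_distance_matrix,
    empirical_left_p,
    simulate_panel,
    standardize_columns,
    target_score_matrix,
)


def small_params(seed: int = 0, rho: float = 0.9, **overrides) -> SimParams:
    """Reduced panels (24/10/12 RBPs, 3 modules of 4) for fast unit tests."""
    base = dict(
        seed=seed,
        rho=rho,
        n_eclip=24,
        n_bioid=10,
        n_perturb=12,
        n_overlap=4,
        n_features={"eclip": 120, "bioid": 100, "perturbseq": 120},
        n_modules=3,
        module_size=4,
        regulon_size=12,
        function_set_size=10,
        signature_size=12,
        n_decoy_sets=3,
        cells_per_guide=40,
        control_cells=40,
    )
    base.update(overrides)
    return SimParams(**base)


def pipeline_products(params: SimParams):
    """Run simulate -> scores -> distances -> empirical p -> integrated map."""
    tables, truth = simulate_panel(params)
    pmats = {}
    for modality, table in tables.items():
        z = standardize_columns(target_score_matrix(table))
        pmats[modality] = empirical_left_p(cosine_distance_matrix(z))
    return tables, truth, pmats, build_irim(pmats)


@pytest.fixture(scope="session")
def study_pipeline():
    """Full study-condition panels (120/50/68, union 90) built once per session."""
    return pipeline_products(SimParams(seed=1))


@pytest.fixture(scope="session")
def small_pipeline():
    return pipeline_products(small_params(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def random_integrated_map(rng, n: int):
    """A symmetric random map over n RBPs (k=2 everywhere), for null tests."""
    from irimap.integrate import IntegratedMap

    ids = [f"R{i:03d}" for i in range(n)]
    v = rng.random((n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, np.nan)
    return IntegratedMap(
        pd.DataFrame(v, index=ids, columns=ids),
        pd.DataFrame(2, index=ids, columns=ids),
    )
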