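import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import covnet as cv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STANDARD_COVARIATES = ("age", "gender", "cirs", "mean_thickness")


@pytest.fixture(scope="session")
def toy_cohort() -> cv.CohortTable:
    """Deterministic 6-subject, 4-region cohort with two groups of three."""
    rng = np.random.default_rng(42)
    ids = [f"s{i}" for i in range(6)]
    thickness = pd.DataFrame(
        2.5 + 0.1 * rng.standard_normal((6, 4)),
        index=ids,
        columns=["roi_a", "roi_b", "roi_c", "roi_d"],
    )
    return cv.CohortTable(
        thickness=thickness,
        group=pd.Series(["ctrl"] * 3 + ["pat"] * 3, index=ids),
        covariates=pd.DataFrame({"age": rng.uniform(60, 84, 6)}, index=ids),
    )


@pytest.fixture(scope="session")
def default_cohort() -> cv.CohortTable:
    """One default synthetic cohort (68 regions, 25 + 33 subjects)."""
    cohort, _ = cv.generate_cohort(cv.default_spec(seed=7))
    return cohort


@pytest.fixture(scope="session")
def default_networks(default_cohort):
    """Group networks of the default cohort at its minimum density."""
    resid = cv.residualize(default_cohort, STANDARD_COVARIATES)
    assocs = [cv.build_association(resid, g) for g in default_cohort.group_levels]
    d_min = cv.find_min_density(assocs, cv.density_grid())
    return {a.group: cv.threshold_at_density(a, d_min) for a in assocs}


def graph_from_edges(n: int, edges) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    return adj


def star_graph(leaves: int) -> np.ndarray:
    return graph_from_edges(leaves + 1, [(0, i) for i in range(1, leaves + 1)])


def ring_lattice(n: int, k_per_side: int) -> np.ndarray:
    edges = [
        (i, (i + d) % n) for i in range(n) for d in range(1, k_per_side + 1)
    ]
    return graph_from_edges(n, edges)


def complete_graph(n: int) -> np.ndarray:
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    return adj


def as_network(adj: np.ndarray, group: str = "g") -> cv.BinaryNetwork:
    n = adj.shape[0]
    e = int(adj.sum()) // 2
    density = e / (n * (n - 1) / 2) if n > 1 else 0.0
    return cv.BinaryNetwork(adjacency=adj, density=density, group=group)
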