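import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import covnet as cv
from covnet.cohort import CohortError
from covnet.network import edge_count, largest_component_size


def _cohort_from_arrays(thickness, groups, covariates=None):
    ids = [f"s{i}" for i in range(len(thickness))]
    cov = covariates if covariates is not None else {}
    return cv.CohortTable(
        thickness=pd.DataFrame(
            thickness, index=ids, columns=[f"r{j}" for j in range(thickness.shape[1])]
        ),
        group=pd.Series(groups, index=ids),
        covariates=pd.DataFrame(cov, index=pd.Index(ids)),
    )


# -- residualization --------------------------------------------------------


def test_interceptonly_residuals_are_groupwise_centered():
    rng = np.random.default_rng(1)
    thick = 2.5 + 0.1 * rng.standard_normal((10, 3))
    cohort = _cohort_from_arrays(thick, ["a"] * 5 + ["b"] * 5)
    resid = cv.residualize(cohort, ())
    for g in ("a", "b"):
        mask = cohort.group_mask(g)
        expected = thick[mask] - thick[mask].mean(axis=0)
        assert np.allclose(resid.thickness.to_numpy()[mask], expected, atol=1e-12)


def test_thickness_linear_in_covariate_leaves_zero_residuals():
    rng = np.random.default_rng(2)
    age = rng.uniform(60, 84, 12)
    thick = np.column_stack([2.0 + 0.01 * age, 2.5 - 0.005 * age, 2.2 + 0 * age + 0.001 * age])
    cohort = _cohort_from_arrays(thick, ["a"] * 6 + ["b"] * 6, {"age": age})
    resid = cv.residualize(cohort, ("age",))
    assert np.allclose(resid.thickness.to_numpy(), 0.0, atol=1e-10)


def test_residualization_is_idempotent(default_cohort):
    covs = ("age", "gender", "cirs", "mean_thickness")
    once = cv.residualize(default_cohort, covs)
    twice = cv.residualize(once, covs)
    assert np.allclose(
        once.thickness.to_numpy(), twice.thickness.to_numpy(), atol=1e-10
    )


def test_constant_covariate_is_reported_by_name():
    rng = np.random.default_rng(3)
    thick = 2.5 + 0.1 * rng.standard_normal((8, 3))
    cohort = _cohort_from_arrays(
        thick, ["a"] * 4 + ["b"] * 4, {"site": np.ones(8), "age": rng.uniform(60, 80, 8)}
    )
    with pytest.raises(CohortError, match="site"):
        cv.residualize(cohort, ("site", "age"))


def test_association_invariant_to_affine_covariate_rescaling(default_cohort):
    scaled = default_cohort.covariates.copy()
    scaled["age"] = scaled["age"] * 12.0 + 7.0  # months plus offset
    other = cv.CohortTable(
        thickness=default_cohort.thickness,
        group=default_cohort.group,
        covariates=scaled,
    )
    a1 = cv.build_association(cv.residualize(default_cohort, ("age", "cirs")), "control")
    a2 = cv.build_association(cv.residualize(other, ("age", "cirs")), "control")
    assert np.allclose(a1.values, a2.values, atol=1e-10)


# -- association ------------------------------------------------------------


def test_perfectly_correlated_and_anticorrelated_regions():
    rng = np.random.default_rng(4)
    base = rng.standard_normal(8)
    thick = np.column_stack([2.5 + 0.1 * base, 2.5 + 0.2 * base, 2.5 - 0.1 * base])
    cohort = _cohort_from_arrays(thick, ["a"] * 4 + ["b"] * 4)
    resid = cv.residualize(cohort, ())
    assoc = cv.build_association(resid, "a")
    assert assoc.values[0, 1] == pytest.approx(1.0)
    assert assoc.values[0, 2] == pytest.approx(-1.0)
    assert np.all(np.diag(assoc.values) == 0)


def test_zero_variance_region_is_an_error():
    rng = np.random.default_rng(5)
    thick = 2.5 + 0.1 * rng.standard_normal((8, 3))
    thick[:4, 1] = 2.2  # constant within group "a"
    cohort = _cohort_from_arrays(thick, ["a"] * 4 + ["b"] * 4)
    with pytest.raises(CohortError, match="r1"):
        cv.build_association(cohort.with_thickness(cohort.thickness), "a")


def test_association_recovers_twoblock_generating_covariance():
    """Monte-Carlo: empirical R within ±0.05 of the generating rho at n=200."""
    rng = np.random.default_rng(6)
    n, rho = 200, 0.8
    c = np.full((4, 4), 0.0)
    c[:2, :2] = rho
    c[2:, 2:] = rho
    np.fill_diagonal(c, 1.0)
    z = rng.multivariate_normal(np.zeros(4), c, size=2 * n)
    thick = 2.5 + 0.1 * z
    cohort = _cohort_from_arrays(thick, ["a"] * n + ["b"] * n)
    assoc = cv.build_association(cv.residualize(cohort, ()), "a")
    assert assoc.values[0, 1] == pytest.approx(rho, abs=0.05)
    assert assoc.values[2, 3] == pytest.approx(rho, abs=0.05)
    assert assoc.values[0, 2] == pytest.approx(0.0, abs=0.05)


# -- thresholding -----------------------------------------------------------


def _assoc_from_matrix(values, group="g"):
    np.fill_diagonal(values, 0.0)
    labels = tuple(f"r{i}" for i in range(values.shape[0]))
    return cv.AssociationMatrix(values=values, labels=labels, group=group, n_subjects=10)


def test_density_ten_percent_of_68_regions_gives_228_edges():
    rng = np.random.default_rng(7)
    m = rng.uniform(-1, 1, (68, 68))
    m = (m + m.T) / 2
    assoc = _assoc_from_matrix(m)
    net = cv.threshold_at_density(assoc, 0.10)
    assert net.n_edges == 228  # round(0.10 * 68 * 67 / 2)


def test_density_one_gives_complete_graph():
    rng = np.random.default_rng(8)
    m = rng.uniform(-1, 1, (9, 9))
    m = (m + m.T) / 2
    net = cv.threshold_at_density(_assoc_from_matrix(m), 1.0)
    assert net.n_edges == 9 * 8 // 2


def test_top1_selection_keeps_only_strongest_pair():
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 0.9
    m[0, 2] = m[2, 0] = 0.5
    m[1, 2] = m[2, 1] = 0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = cv.threshold_at_density(_assoc_from_matrix(m), 1 / 3)
    assert net.n_edges == 1 and net.adjacency[0, 1]


def test_signed_ranking_never_selects_strong_negative_edges():
    m = np.zeros((4, 4))
    m[0, 1] = m[1, 0] = -0.95
    m[0, 2] = m[2, 0] = 0.2
    m[1, 3] = m[3, 1] = 0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = cv.threshold_at_density(_assoc_from_matrix(m.copy()), 2 / 6)
        net_abs = cv.threshold_at_density(_assoc_from_matrix(m.copy()), 2 / 6, absolute=True)
    assert not net.adjacency[0, 1]
    assert net_abs.adjacency[0, 1]


def test_invalid_density_and_edge_budget_warning():
    rng = np.random.default_rng(9)
    m = rng.uniform(-1, 1, (10, 10))
    m = (m + m.T) / 2
    assoc = _assoc_from_matrix(m)
    with pytest.raises(ValueError):
        cv.threshold_at_density(assoc, 1.5)
    with pytest.warns(UserWarning, match="cannot be connected"):
        cv.threshold_at_density(assoc, 0.05)


@given(st.integers(min_value=0, max_value=10_000))
def test_thresholded_edge_sets_are_nested_in_density(seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(-1, 1, (12, 12))
    m = (m + m.T) / 2
    assoc = _assoc_from_matrix(m)
    grid = [0.1, 0.25, 0.5, 0.9]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nets = [cv.threshold_at_density(assoc, d) for d in grid]
    for lo, hi in zip(nets, nets[1:]):
        assert not np.any(lo.adjacency & ~hi.adjacency)  # subset
    sizes = [largest_component_size(n.adjacency) for n in nets]
    assert sizes == sorted(sizes)  # largest component non-decreasing


# -- minimum density --------------------------------------------------------


def test_min_density_from_planted_spanning_tree():
    """Top R−1 correlations forming a tree connect at the first density with E >= R−1."""
    rng = np.random.default_rng(10)
    r = 20
    m = rng.uniform(0.0, 0.4, (r, r))
    m = (m + m.T) / 2
    order = rng.permutation(r)
    for a, b in zip(order, order[1:]):  # random spanning path gets the top values
        m[a, b] = m[b, a] = rng.uniform(0.9, 1.0)
    assoc = _assoc_from_matrix(m)
    grid = np.array([0.05, 0.10, 0.15, 0.20])
    expected = next(d for d in grid if edge_count(r, d) >= r - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert cv.find_min_density([assoc], grid) == pytest.approx(expected)


def test_min_density_is_max_over_groups(default_cohort):
    resid = cv.residualize(default_cohort, ("age", "gender", "cirs", "mean_thickness"))
    assocs = [cv.build_association(resid, g) for g in default_cohort.group_levels]
    grid = cv.density_grid()
    joint = cv.find_min_density(assocs, grid)
    singles = [cv.find_min_density([a], grid) for a in assocs]
    assert joint == pytest.approx(max(singles))


def test_min_density_error_reports_component_sizes():
    m = np.zeros((6, 6))
    m[0, 1] = m[1, 0] = 0.9
    m[2, 3] = m[3, 2] = 0.8
    m[4, 5] = m[5, 4] = 0.7
    assoc = _assoc_from_matrix(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with pytest.raises(ValueError, match="largest component"):
            cv.find_min_density([assoc], np.array([0.2]))


def test_density_grid_contract():
    grid = cv.density_grid(0.10, 0.20, 0.01)
    assert len(grid) == 11
    assert grid[0] == 0.10 and grid[-1] == 0.20
    assert np.all(np.diff(grid) > 0)
    with pytest.raises(ValueError):
        cv.density_grid(0.2, 0.1, 0.01)
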