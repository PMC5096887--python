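"""Structural covariance network construction.

Pipeline stage 1: residualize regional thickness against nuisance covariates
(ordinary least squares with intercept, fitted within each group by default),
correlate the residuals across subjects to obtain one region × region Pearson
association matrix per group, then binarize each matrix over a grid of edge
densities by keeping the strongest signed correlations.  The minimum density
D_min is the smallest grid density at which every group's network forms a
single connected component — the paper-style anchor density for resilience
and hub analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .cohort import CohortError, CohortTable, MEAN_THICKNESS

__all__ = [
    "AssociationMatrix",
    "BinaryNetwork",
    "density_grid",
    "residualize",
    "build_association",
    "threshold_at_density",
    "find_min_density",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric Pearson correlation matrix of residualized thickness.

    ``values`` is R × R with zero diagonal (self-connections removed) and all
    off-diagonal entries in [-1, 1].
    """

    values: np.ndarray
    labels: tuple[str, ...]
    group: str
    n_subjects: int

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"association matrix must be square, got {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal (self-connections) must be exactly 0")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected unweighted graph from density thresholding.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal;
    ``density`` is the requested edge density (the realized edge count is
    ``round(density * R(R-1)/2)``).
    """

    adjacency: np.ndarray
    density: float
    group: str
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.dtype != bool:
            object.__setattr__(self, "adjacency", a.astype(bool))
            a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency diagonal must be empty (no self-loops)")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"r{i}" for i in range(a.shape[0]))
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def is_connected(self) -> bool:
        return _n_components(self.adjacency) == 1

    def to_graph(self) -> nx.Graph:
        """networkx view with integer nodes 0..R-1 (region order preserved)."""
        g: nx.Graph = nx.from_numpy_array(self.adjacency.astype(np.uint8))
        return g


def largest_component_size(adj: np.ndarray) -> int:
    """Size of the largest connected component (dense BFS; fast for R ~ 100)."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    unvisited = np.ones(n, dtype=bool)
    best = 0
    while unvisited.any():
        comp = np.zeros(n, dtype=bool)
        comp[int(np.argmax(unvisited))] = True
        frontier = comp.copy()
        while frontier.any():
            frontier = adj[frontier].any(axis=0) & ~comp
            comp |= frontier
        best = max(best, int(comp.sum()))
        unvisited &= ~comp
    return best


def _n_components(adj: np.ndarray) -> int:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    unvisited = np.ones(n, dtype=bool)
    count = 0
    while unvisited.any():
        comp = np.zeros(n, dtype=bool)
        comp[int(np.argmax(unvisited))] = True
        frontier = comp.copy()
        while frontier.any():
            frontier = adj[frontier].any(axis=0) & ~comp
            comp |= frontier
        count += 1
        unvisited &= ~comp
    return count


# -- density grid -----------------------------------------------------------


def density_grid(dmin: float = 0.10, dmax: float = 0.20, step: float = 0.01) -> np.ndarray:
    """Strictly increasing density grid in (0, 1), endpoints inclusive.

    Built in integer arithmetic (thousandths) so 0.10:0.01:0.20 yields exactly
    eleven points.
    """
    lo, hi, st = (int(round(x * 1000)) for x in (dmin, dmax, step))
    if st <= 0 or lo <= 0 or hi >= 1000 or lo > hi:
        raise ValueError(f"invalid density grid ({dmin}, {dmax}, {step})")
    return np.arange(lo, hi + 1, st) / 1000.0


# -- residualization --------------------------------------------------------


def residualize(
    cohort: CohortTable,
    covariate_names: Sequence[str],
    *,
    per_group: bool = True,
) -> CohortTable:
    """Replace thickness by OLS residuals on the named covariates.

    Each region's thickness is regressed (with intercept) on the covariate
    columns and replaced by the residual of that fit.  By default the
    regression is fitted within each group separately, so each group's
    covariance reflects only its own covariate-adjusted variation; pass
    ``per_group=False`` to pool.  ``mean_thickness`` is computed on the fly
    from the thickness rows if requested but absent.  Residualization is
    idempotent and invariant to affine rescaling of any covariate.
    """
    cohort = cohort.ensure_mean_thickness() if MEAN_THICKNESS in covariate_names else cohort
    missing = [c for c in covariate_names if c not in cohort.covariates.columns]
    if missing:
        raise CohortError(f"covariates absent from cohort: {missing}")

    y = cohort.thickness.to_numpy(dtype=float)
    x = cohort.covariates[list(covariate_names)].to_numpy(dtype=float)
    groups = (
        [cohort.group_mask(g) for g in cohort.group_levels]
        if per_group
        else [np.ones(len(y), dtype=bool)]
    )
    resid = np.empty_like(y)
    for mask in groups:
        if mask.sum() < len(covariate_names) + 2:
            raise CohortError(
                f"need >= {len(covariate_names) + 2} subjects per fitted model, "
                f"got {int(mask.sum())}"
            )
        xg = x[mask]
        const = [
            name
            for name, col in zip(covariate_names, xg.T)
            if np.ptp(col) == 0
        ]
        if const:
            raise CohortError(
                f"rank-deficient design: covariate(s) {const} constant within a fit"
            )
        resid[mask] = _ols_residuals(xg, y[mask])
    out = cohort.thickness.copy()
    out.loc[:, :] = resid
    return cohort.with_thickness(out)


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of y (n × R) on [1, x] via a thin QR projection."""
    design = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CohortError("rank-deficient design: collinear covariates")
    q, _ = np.linalg.qr(design)
    return y - q @ (q.T @ y)


# -- association ------------------------------------------------------------


def build_association(cohort: CohortTable, group: str) -> AssociationMatrix:
    """Pearson correlation matrix across subjects of one group.

    The cohort is expected to hold residualized thickness; the diagonal is
    set to zero.  A region with zero variance within the group is an error
    (its correlations are undefined).
    """
    if group not in cohort.group_levels:
        raise CohortError(f"unknown group {group!r}; levels are {cohort.group_levels}")
    mask = cohort.group_mask(group)
    values = cohort.thickness.to_numpy(dtype=float)[mask]
    if values.shape[0] < 3:
        raise CohortError("Pearson correlation needs >= 3 subjects")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        dead = [cohort.region_names[i] for i in np.flatnonzero(sd == 0)]
        raise CohortError(f"zero residual variance in region(s) {dead}")
    corr = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return AssociationMatrix(
        values=corr,
        labels=tuple(cohort.region_names),
        group=group,
        n_subjects=int(mask.sum()),
    )


# -- thresholding -----------------------------------------------------------


def edge_count(n_regions: int, density: float) -> int:
    """round-half-away-from-zero of density × R(R−1)/2."""
    return int(np.floor(density * n_regions * (n_regions - 1) / 2.0 + 0.5))


def ranked_pairs(values: np.ndarray, *, absolute: bool = False) -> np.ndarray:
    """Upper-triangle pairs ordered by descending correlation.

    Ties are broken by ascending (row, column) index so thresholding is fully
    deterministic.  With ``absolute=True`` pairs are ranked by |R| instead of
    signed R.
    """
    rows, cols = np.triu_indices(values.shape[0], k=1)
    key = np.abs(values[rows, cols]) if absolute else values[rows, cols]
    order = np.lexsort((cols, rows, -key))
    return np.column_stack([rows[order], cols[order]])


def threshold_at_density(
    assoc: AssociationMatrix,
    density: float,
    *,
    absolute: bool = False,
) -> BinaryNetwork:
    """Binarize by keeping the E = round(density·R(R−1)/2) strongest edges.

    Signed ranking is the default (strong negative correlations are never
    edges); ``absolute=True`` ranks by magnitude.  Warns when the edge budget
    cannot connect the graph (E < R−1).
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    r = assoc.n_regions
    e = edge_count(r, density)
    if e < r - 1:
        warnings.warn(
            f"density {density} gives {e} edges < R-1 = {r - 1}; "
            "the network cannot be connected",
            stacklevel=2,
        )
    pairs = ranked_pairs(assoc.values, absolute=absolute)[:e]
    adj = np.zeros((r, r), dtype=bool)
    adj[pairs[:, 0], pairs[:, 1]] = True
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, density=density, group=assoc.group, labels=assoc.labels)


# -- minimum density --------------------------------------------------------


def find_min_density(
    assoc_list: Iterable[AssociationMatrix],
    grid: np.ndarray,
    *,
    absolute: bool = False,
) -> float:
    """Smallest grid density at which every group's network is one component.

    Guarantees that none of the analysed networks is fragmented.  Raises with
    per-group largest-component sizes at the top of the grid when no grid
    density suffices.
    """
    assocs = list(assoc_list)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("density grid is empty")
    for d in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nets = [threshold_at_density(a, float(d), absolute=absolute) for a in assocs]
        if all(net.is_connected for net in nets):
            return float(d)
    sizes = {
        a.group: largest_component_size(
            threshold_at_density(a, float(grid[-1]), absolute=absolute).adjacency
        )
        for a in assocs
    }
    raise ValueError(
        "no grid density connects every group; largest component at density "
        f"{grid[-1]}: {sizes} of {assocs[0].n_regions} nodes"
    )
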