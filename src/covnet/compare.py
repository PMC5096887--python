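"""Permutation-based group comparison of network measures.

Group labels carry no exchangeable-unit structure beyond the subject, so the
null distribution of any between-group network difference is obtained by
shuffling group labels across subjects (preserving group sizes) and
recomputing the *entire* downstream pipeline — covariate residualization,
Pearson association, density thresholding, metric — for every permutation.
Differences are compared per density and as the area under the
metric-versus-density curve (AUC), which summarizes the comparison in a
single p-value that is insensitive to the choice of any one threshold.

All p-values are two-tailed with the add-one correction
p = (1 + #{|null| >= |observed|}) / (n_perm + 1), so p is never zero and the
observed statistic is counted in its own null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import metrics as gm
from .cohort import CohortTable
from .network import (
    BinaryNetwork,
    build_association,
    density_grid,
    edge_count,
    find_min_density,
    largest_component_size,
    residualize,
)

logger = logging.getLogger("covnet")

__all__ = [
    "PermutationResult",
    "compare_metrics",
    "permute_compare",
    "auc_compare",
    "nodal_compare",
    "metric_curves",
]

_SIGMA_FAMILY = {"gamma", "lambda", "sigma"}

#: metrics whose value is undefined (or not comparable) on a fragmented
#: network; densities where an observed group network fragments are dropped
#: for these metrics only.  Count-based measures (clustering, transitivity,
#: modularity) and the efficiency measures are well defined on any graph.
CONNECTIVITY_REQUIRED = {"char_path_length", "gamma", "lambda", "sigma"}


@dataclass
class PermutationResult:
    """Observed and null between-group differences for one metric.

    ``observed_diff`` and the null rows are group A − group B where A is the
    alphabetically first group level.  ``densities`` holds only the densities
    kept for comparison (densities where an observed group network fragments
    are dropped and listed in ``dropped_densities``).
    """

    metric_name: str
    groups: tuple[str, str]
    densities: np.ndarray
    curve_a: np.ndarray
    curve_b: np.ndarray
    observed_diff: np.ndarray
    auc_a: float
    auc_b: float
    auc_diff: float
    null_diffs: np.ndarray  # n_perm × n_densities
    null_auc_diffs: np.ndarray
    p_per_density: np.ndarray
    p_auc: float
    ci_band: np.ndarray  # 2 × n_densities (2.5th / 97.5th null percentiles)
    n_perm: int
    seed: int | None
    dropped_densities: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.densities,
                f"{self.groups[0]}": self.curve_a,
                f"{self.groups[1]}": self.curve_b,
                "difference": self.observed_diff,
                "p": self.p_per_density,
                "null_lo": self.ci_band[0],
                "null_hi": self.ci_band[1],
            }
        )


# -- fast inner pipeline ----------------------------------------------------


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _corr(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(c, 0.0)
    return c


def _eval_one(
    adj: np.ndarray,
    names: Sequence[str],
    rng: np.random.Generator,
    n_refs: int,
    swap_factor: int,
) -> dict[str, float]:
    out: dict[str, float] = {}
    need_sw = any(m in _SIGMA_FAMILY for m in names)
    if "char_path_length" in names or "global_efficiency" in names:
        # one BFS shared by both path-based measures
        d = gm._distances(adj)
        off = ~np.eye(adj.shape[0], dtype=bool)
        if "char_path_length" in names:
            finite = np.isfinite(d) & off
            out["char_path_length"] = float(d[finite].mean()) if finite.any() else float("nan")
        if "global_efficiency" in names:
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
            out["global_efficiency"] = float(inv[off].mean())
    if "clustering_coefficient" in names or "transitivity" in names:
        clus = gm.clustering_and_transitivity(adj)
        out["clustering_coefficient"] = clus.mean_clustering
        out["transitivity"] = clus.transitivity
    if "local_efficiency" in names:
        out["local_efficiency"] = gm.local_efficiency(adj)
    if "modularity" in names:
        out["modularity"] = gm.modularity(adj)[0] if adj.any() else float("nan")
    if need_sw:
        net = BinaryNetwork(adjacency=adj.copy(), density=float(adj.sum()) / (adj.shape[0] * (adj.shape[0] - 1)), group="_")
        refs = gm.random_reference(net, seed=rng, n_networks=n_refs, swap_factor=swap_factor)
        sw = gm.small_world(net, refs)
        out["gamma"], out["lambda"], out["sigma"] = sw.gamma, sw.lam, sw.sigma
    return {m: out[m] for m in names}


def _group_curves(
    y: np.ndarray,
    x: np.ndarray,
    masks: Sequence[np.ndarray],
    grid: np.ndarray,
    names: Sequence[str],
    rng: np.random.Generator,
    n_refs: int,
    swap_factor: int,
    rows: np.ndarray,
    cols: np.ndarray,
    pooled: bool = False,
    check_connectivity: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Metric curves for each group mask; returns (curves, connected) arrays.

    curves: n_groups × n_metrics × n_densities; connected: n_groups × n_densities.
    With ``pooled=True`` the covariate regression is fitted across all
    subjects at once instead of within each mask.
    """
    r = y.shape[1]
    e_counts = [edge_count(r, float(d)) for d in grid]
    curves = np.empty((len(masks), len(names), len(grid)))
    connected = (
        np.empty((len(masks), len(grid)), dtype=bool) if check_connectivity else None
    )
    resid_full = _residuals(y, x) if pooled else None
    for gi, mask in enumerate(masks):
        resid = resid_full[mask] if pooled else _residuals(y[mask], x[mask])
        corr = _corr(resid)
        key = corr[rows, cols]
        order = np.lexsort((cols, rows, -key))
        adj = np.zeros((r, r), dtype=bool)
        prev = 0
        for di, e in enumerate(e_counts):
            sel = order[prev:e]
            adj[rows[sel], cols[sel]] = True
            adj[cols[sel], rows[sel]] = True
            prev = e
            vals = _eval_one(adj, names, rng, n_refs, swap_factor)
            curves[gi, :, di] = [vals[m] for m in names]
            if check_connectivity:
                connected[gi, di] = largest_component_size(adj) == r
    return curves, connected


def metric_curves(
    cohort: CohortTable,
    metric_names: Sequence[str],
    grid: np.ndarray | None = None,
    covariates: Sequence[str] = (),
    *,
    per_group: bool = True,
    n_refs: int = 20,
    swap_factor: int = 100,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Observed metric-versus-density curves per group (no inference).

    Returns one DataFrame per metric with a row per density and a column per
    group.  Small-world terms (gamma/lambda/sigma) use ``n_refs`` seeded
    rewired references per network.
    """
    grid = density_grid() if grid is None else np.asarray(grid, dtype=float)
    unknown = [m for m in metric_names if m not in gm.GLOBAL_METRIC_NAMES]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {gm.GLOBAL_METRIC_NAMES}")
    cohort = cohort.ensure_mean_thickness() if "mean_thickness" in covariates else cohort
    # validate covariates and design through the strict public path
    residualize(cohort, covariates, per_group=per_group)
    levels = cohort.group_levels
    y = cohort.thickness.to_numpy(dtype=float)
    x = cohort.covariates[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    masks = [cohort.group_mask(g) for g in levels]
    rng = np.random.default_rng(seed)
    rows, cols = np.triu_indices(cohort.n_regions, k=1)
    curves, _ = _group_curves(
        y, x, masks, grid, list(metric_names), rng, n_refs, swap_factor, rows, cols,
        pooled=not per_group,
    )
    return {
        m: pd.DataFrame(
            {levels[0]: curves[0, i], levels[1]: curves[1, i]}, index=pd.Index(grid, name="density")
        )
        for i, m in enumerate(metric_names)
    }


def _pvalue(null: np.ndarray, observed: np.ndarray | float) -> np.ndarray | float:
    """Two-tailed add-one permutation p."""
    null = np.atleast_1d(np.asarray(null, dtype=float))
    n = null.shape[0]
    count = (np.abs(null) >= np.abs(observed) - 1e-15).sum(axis=0)
    return (1.0 + count) / (n + 1.0)


def compare_metrics(
    cohort: CohortTable,
    metric_names: Sequence[str],
    grid: np.ndarray | None = None,
    covariates: Sequence[str] = (),
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    per_group: bool = True,
    n_refs: int = 10,
    swap_factor: int = 100,
) -> dict[str, PermutationResult]:
    """Permutation comparison of several metrics sharing one permutation stream.

    Labels are shuffled before residualization, so the covariate regressions
    are honestly recomputed for every permutation.  Densities at which either
    observed group network fragments are dropped from the comparison (the
    remaining grid still feeds the AUC).  Fully reproducible for a fixed seed.
    """
    grid = density_grid() if grid is None else np.asarray(grid, dtype=float)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives unstable p-values", stacklevel=2)
    names = list(metric_names)
    unknown = [m for m in names if m not in gm.GLOBAL_METRIC_NAMES]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}")
    cohort = cohort.ensure_mean_thickness() if "mean_thickness" in covariates else cohort
    residualize(cohort, covariates, per_group=per_group)

    levels = cohort.group_levels
    y = cohort.thickness.to_numpy(dtype=float)
    x = cohort.covariates[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    labels = (cohort.group == levels[1]).to_numpy()  # False = A, True = B
    rows, cols = np.triu_indices(cohort.n_regions, k=1)
    rng = np.random.default_rng(seed)

    def curves_for(lab: np.ndarray, check: bool = False) -> tuple[np.ndarray, np.ndarray | None]:
        return _group_curves(
            y, x, [~lab, lab], grid, names, rng, n_refs, swap_factor, rows, cols,
            pooled=not per_group, check_connectivity=check,
        )

    obs_curves, obs_conn = curves_for(labels, check=True)
    conn_all = obs_conn.all(axis=0)

    null = np.empty((n_perm, len(names), len(grid)))
    for b in range(n_perm):
        perm = rng.permutation(labels)
        c, _ = curves_for(perm)
        null[b] = c[0] - c[1]

    results: dict[str, PermutationResult] = {}
    for i, m in enumerate(names):
        keep = conn_all if m in CONNECTIVITY_REQUIRED else np.ones(len(grid), dtype=bool)
        dropped = grid[~keep]
        if dropped.size:
            logger.info(
                "%s: dropping densities %s (an observed group network is fragmented)",
                m,
                np.round(dropped, 4).tolist(),
            )
        if keep.sum() < 2:
            raise ValueError(
                f"{m}: fewer than 2 densities with connected observed networks; "
                "AUC undefined"
            )
        kept_grid = grid[keep]
        a, bb = obs_curves[0, i, keep], obs_curves[1, i, keep]
        diff = a - bb
        auc_a = float(np.trapezoid(a, kept_grid))
        auc_b = float(np.trapezoid(bb, kept_grid))
        null_m = null[:, i, :][:, keep]
        null_auc = np.trapezoid(null_m, kept_grid, axis=1)
        results[m] = PermutationResult(
            metric_name=m,
            groups=(levels[0], levels[1]),
            densities=kept_grid,
            curve_a=a,
            curve_b=bb,
            observed_diff=diff,
            auc_a=auc_a,
            auc_b=auc_b,
            auc_diff=auc_a - auc_b,
            null_diffs=null_m,
            null_auc_diffs=null_auc,
            p_per_density=np.asarray(_pvalue(null_m, diff)),
            p_auc=float(_pvalue(null_auc, auc_a - auc_b)),
            ci_band=np.percentile(null_m, [2.5, 97.5], axis=0),
            n_perm=n_perm,
            seed=seed,
            dropped_densities=dropped,
        )
    return results


def permute_compare(
    cohort: CohortTable,
    metric: str,
    grid: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    covariates: Sequence[str] = (),
    **kwargs,
) -> PermutationResult:
    """Single-metric convenience wrapper around :func:`compare_metrics`."""
    return compare_metrics(
        cohort, [metric], grid=grid, covariates=covariates, n_perm=n_perm, seed=seed, **kwargs
    )[metric]


def auc_compare(result: PermutationResult) -> tuple[float, float]:
    """Observed AUC difference and its permutation p (trapezoidal integral).

    The grid may be non-uniform; a single retained density is an error.
    """
    if result.densities.size < 2:
        raise ValueError("AUC needs metric values at >= 2 densities")
    return result.auc_diff, result.p_auc


# -- nodal comparison -------------------------------------------------------

_NODAL = ("degree", "clustering", "betweenness")


def _nodal_values(adj: np.ndarray, names: Sequence[str]) -> np.ndarray:
    rows = []
    clus = gm.clustering_and_transitivity(adj).nodal if "clustering" in names else None
    for m in names:
        if m == "degree":
            rows.append(gm.degrees(adj).astype(float))
        elif m == "clustering":
            rows.append(clus)
        elif m == "betweenness":
            rows.append(gm.betweenness(adj))
        else:
            raise ValueError(f"unknown nodal metric {m!r}")
    return np.stack(rows)


def nodal_compare(
    cohort: CohortTable,
    density: float,
    covariates: Sequence[str] = (),
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    metrics: Sequence[str] = _NODAL,
    per_group: bool = True,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region permutation comparison with BH-FDR correction.

    Compares nodal degree, clustering and betweenness between groups at one
    density (which must be at or above the minimum density for the cohort),
    returning a long DataFrame with raw p and BH-adjusted q per region within
    each metric.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives unstable p-values", stacklevel=2)
    grid = density_grid() if grid is None else np.asarray(grid, dtype=float)
    cohort = cohort.ensure_mean_thickness() if "mean_thickness" in covariates else cohort
    resid = residualize(cohort, covariates, per_group=per_group)
    assocs = [build_association(resid, g) for g in cohort.group_levels]
    dmin = find_min_density(assocs, grid)
    if density < dmin - 1e-12:
        raise ValueError(f"density {density} is below D_min = {dmin}")

    levels = cohort.group_levels
    y = cohort.thickness.to_numpy(dtype=float)
    x = cohort.covariates[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))
    labels = (cohort.group == levels[1]).to_numpy()
    rows, cols = np.triu_indices(cohort.n_regions, k=1)
    r = cohort.n_regions
    e = edge_count(r, density)
    names = list(metrics)

    resid_full = _residuals(y, x) if not per_group else None

    def nodal_for(lab: np.ndarray) -> np.ndarray:
        vals = []
        for mask in (~lab, lab):
            resid = resid_full[mask] if resid_full is not None else _residuals(y[mask], x[mask])
            corr = _corr(resid)
            key = corr[rows, cols]
            order = np.lexsort((cols, rows, -key))[:e]
            adj = np.zeros((r, r), dtype=bool)
            adj[rows[order], cols[order]] = True
            adj |= adj.T
            vals.append(_nodal_values(adj, names))
        return vals[0] - vals[1]  # n_metrics × R

    rng = np.random.default_rng(seed)
    observed = nodal_for(labels)
    null = np.empty((n_perm,) + observed.shape)
    for b in range(n_perm):
        null[b] = nodal_for(rng.permutation(labels))
    p = np.asarray(_pvalue(null, observed))

    frames = []
    for i, m in enumerate(names):
        q = multipletests(p[i], method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "metric": m,
                    "region": cohort.region_names,
                    "difference": observed[i],
                    "p": p[i],
                    "q": q,
                    "significant": q < 0.05,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
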