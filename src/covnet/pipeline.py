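"""End-to-end analysis orchestration from a single run configuration.

``run_all`` executes the full workflow on any valid cohort table:
residualize → group association matrices → minimum density → density-grid
thresholding → global metric curves → permutation/AUC comparisons → nodal
comparisons → resilience (random and targeted, optional covariate-adjusted
variant) → hub identification, writing every result as labeled CSV plus a
JSON manifest recording the seed, configuration hash and library versions.

All randomness flows from one master seed through named substreams, so each
component (permutations, rewirings, attack orders, simulation) is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSchema, CohortTable, read_cohort, write_matrix
from .compare import compare_metrics, metric_curves, nodal_compare
from .hubs import identify_hubs
from .metrics import GLOBAL_METRIC_NAMES
from .network import (
    build_association,
    density_grid,
    find_min_density,
    residualize,
    threshold_at_density,
)
from .resilience import compare_resilience

logger = logging.getLogger("covnet")

__all__ = ["RunConfig", "run_all", "substream"]

#: metrics whose permutation comparison does not need rewired references
PERMUTABLE_METRICS = (
    "char_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "local_efficiency",
    "transitivity",
    "modularity",
)


def substream(master_seed: int, name: str) -> np.random.SeedSequence:
    """Named, reproducible child seed sequence of the master seed."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream(master_seed, name))


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis."""

    input: str
    schema: CohortSchema
    covariates: tuple[str, ...] = ("age", "gender", "cirs", "mean_thickness")
    grid: tuple[float, float, float] = (0.10, 0.20, 0.01)
    n_perm: int = 1000
    seed: int = 0
    metrics: tuple[str, ...] = GLOBAL_METRIC_NAMES
    resilience_modes: tuple[str, ...] = ("random", "targeted")
    resilience_repeats: int = 50
    extra_covariates: tuple[str, ...] = ()
    n_refs: int = 20
    hub_z: float = 2.0
    per_group_residuals: bool = True
    output_dir: str = "covnet-results"

    def __post_init__(self) -> None:
        density_grid(*self.grid)  # validates
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        unknown = [m for m in self.metrics if m not in GLOBAL_METRIC_NAMES]
        if unknown:
            raise ValueError(f"unknown metrics in config: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        schema = CohortSchema(**raw.pop("schema"))
        grid = raw.pop("grid", None)
        kwargs: dict[str, Any] = {"schema": schema}
        if grid is not None:
            kwargs["grid"] = (grid["min"], grid["max"], grid["step"])
        for key in (
            "input", "covariates", "n_perm", "seed", "metrics", "resilience_modes",
            "resilience_repeats", "extra_covariates", "n_refs", "hub_z",
            "per_group_residuals", "output_dir",
        ):
            if key in raw:
                value = raw[key]
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_curves(curves: dict[str, pd.DataFrame], path: Path) -> None:
    wide = pd.concat(
        {m: df for m, df in curves.items()}, axis=1
    )
    wide.columns = [f"{m}:{g}" for m, g in wide.columns]
    wide.to_csv(path)


def run_all(config: RunConfig, cohort: CohortTable | None = None) -> dict[str, Any]:
    """Execute the full pipeline; returns the in-memory result bundle.

    Any stage failure aborts with the stage name recorded in a
    partial-results manifest so completed outputs remain usable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = density_grid(*config.grid)
    manifest: dict[str, Any] = {
        "covnet_version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "grid": grid.tolist(),
        "covariates": list(config.covariates),
        "stages_completed": [],
        "outputs": [],
    }
    bundle: dict[str, Any] = {"manifest": manifest}
    stage = "read"

    def done(name: str, *files: Path) -> None:
        manifest["stages_completed"].append(name)
        manifest["outputs"].extend(str(f) for f in files)

    try:
        if cohort is None:
            cohort = read_cohort(config.input, config.schema)
        bundle["cohort"] = cohort
        done("read")

        stage = "residualize"
        resid = residualize(
            cohort, config.covariates, per_group=config.per_group_residuals
        )
        done("residualize")

        stage = "association"
        assocs = {g: build_association(resid, g) for g in cohort.group_levels}
        files = []
        for g, a in assocs.items():
            f = out / f"association_{g}.csv"
            write_matrix(a.values, list(a.labels), f)
            files.append(f)
        bundle["associations"] = assocs
        done("association", *files)

        stage = "min_density"
        d_min = find_min_density(assocs.values(), grid)
        manifest["d_min"] = d_min
        bundle["d_min"] = d_min
        done("min_density")

        stage = "threshold"
        nets = {g: threshold_at_density(a, d_min) for g, a in assocs.items()}
        files = []
        for g, net in nets.items():
            f = out / f"adjacency_dmin_{g}.csv"
            write_matrix(net.adjacency.astype(int), list(net.labels), f)
            files.append(f)
        bundle["networks_dmin"] = nets
        done("threshold", *files)

        stage = "metric_curves"
        curves = metric_curves(
            cohort,
            config.metrics,
            grid,
            config.covariates,
            per_group=config.per_group_residuals,
            n_refs=config.n_refs,
            seed=substream(config.seed, "curves").generate_state(1)[0] % (2**31),
        )
        f = out / "metric_curves.csv"
        _write_curves(curves, f)
        bundle["curves"] = curves
        done("metric_curves", f)

        stage = "permutation"
        perm_metrics = [m for m in config.metrics if m in PERMUTABLE_METRICS]
        results = compare_metrics(
            cohort,
            perm_metrics,
            grid,
            config.covariates,
            n_perm=config.n_perm,
            seed=int(substream(config.seed, "permutation").generate_state(1)[0] % (2**31)),
            per_group=config.per_group_residuals,
        )
        files = []
        auc_rows = []
        for m, res in results.items():
            f = out / f"compare_{m}.csv"
            res.summary().to_csv(f, index=False)
            files.append(f)
            auc_rows.append(
                {
                    "metric": m,
                    f"auc_{res.groups[0]}": res.auc_a,
                    f"auc_{res.groups[1]}": res.auc_b,
                    "auc_difference": res.auc_diff,
                    "p_auc": res.p_auc,
                }
            )
        f = out / "auc_summary.csv"
        pd.DataFrame(auc_rows).to_csv(f, index=False)
        files.append(f)
        bundle["comparisons"] = results
        done("permutation", *files)

        stage = "nodal"
        nodal = nodal_compare(
            cohort,
            d_min,
            config.covariates,
            n_perm=config.n_perm,
            seed=int(substream(config.seed, "nodal").generate_state(1)[0] % (2**31)),
            per_group=config.per_group_residuals,
            grid=grid,
        )
        f = out / "nodal_comparison.csv"
        nodal.to_csv(f, index=False)
        bundle["nodal"] = nodal
        done("nodal", f)

        stage = "resilience"
        res_results = {}
        files = []
        for mode in config.resilience_modes:
            variants = {"": ()}
            if config.extra_covariates:
                variants["_adjusted"] = tuple(config.extra_covariates)
            for suffix, extra in variants.items():
                r = compare_resilience(
                    cohort,
                    mode,
                    n_perm=config.n_perm,
                    seed=int(
                        substream(config.seed, f"resilience-{mode}{suffix}").generate_state(1)[0]
                        % (2**31)
                    ),
                    covariates=config.covariates,
                    extra_covariates=extra or None,
                    grid=grid,
                    n_repeats=config.resilience_repeats,
                    per_group=config.per_group_residuals,
                )
                f = out / f"resilience_{mode}{suffix}.csv"
                r.summary().to_csv(f, index=False)
                files.append(f)
                res_results[f"{mode}{suffix}"] = r
        bundle["resilience"] = res_results
        done("resilience", *files)

        stage = "hubs"
        hub_rows = []
        for g, net in nets.items():
            hs = identify_hubs(net, z_threshold=config.hub_z)
            for region, b, z in hs.hubs:
                hub_rows.append(
                    {"group": g, "density": d_min, "region": region, "betweenness": b, "z": z}
                )
        hubs_df = pd.DataFrame(hub_rows, columns=["group", "density", "region", "betweenness", "z"])
        f = out / "hubs.csv"
        hubs_df.to_csv(f, index=False)
        bundle["hubs"] = hubs_df
        done("hubs", f)

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete; outputs in %s", out)
    return bundle
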