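"""Synthetic two-group cortical-thickness cohorts with known covariance.

The generator instantiates exactly the data model the pipeline assumes:
regional thickness = base level + linear covariate effects + a multivariate
normal regional deviation with a block-structured (modular) correlation
matrix + independent measurement noise.  Within/between-module correlations
are compound-symmetric, so positive semi-definiteness is guaranteed in
closed form whenever 0 <= between_rho <= within_rho < 1, and the strength of
segregation is a single interpretable knob per group.  Optional "hub"
regions receive elevated cross-module correlation, planting high-betweenness
connector nodes.

Defaults mirror a typical late-life structural covariance study: 68 regions
(two-hemisphere Desikan-Killiany-style labels), 25 + 33 subjects, four
modules with within-module correlation 0.6–0.8 over a between-module floor
of 0.1, base thickness 2.3 mm, age drawn uniformly over 60–84 years, a
right-skewed illness-burden score and white-matter-hyperintensity volume.
Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "GroupCovariance",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "plant_segregation_difference",
    "default_spec",
    "null_spec",
    "dk_region_names",
]

_DK34 = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)


def dk_region_names(n_regions: int) -> tuple[str, ...]:
    """Region labels: the 68 two-hemisphere cortical labels when they fit."""
    if n_regions == 68:
        return tuple(f"{h}_{r}" for h in ("lh", "rh") for r in _DK34)
    width = len(str(n_regions))
    return tuple(f"roi{str(i).zfill(width)}" for i in range(n_regions))


@dataclass(frozen=True)
class GroupCovariance:
    """Block correlation parameters of one group.

    ``within_rho`` has one entry per module; ``hub_regions`` are region
    indices whose cross-module correlations are raised to ``hub_rho``.
    """

    within_rho: tuple[float, ...]
    between_rho: float
    hub_regions: tuple[int, ...] = ()
    hub_rho: float = 0.45


def _module_sizes(n_regions: int, n_modules: int) -> list[int]:
    base, extra = divmod(n_regions, n_modules)
    return [base + (1 if i < extra else 0) for i in range(n_modules)]


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous module labels per region."""
    return np.repeat(np.arange(n_modules), _module_sizes(n_regions, n_modules))


def correlation_matrix(cov: GroupCovariance, modules: np.ndarray) -> np.ndarray:
    """Region-by-region generating correlation matrix (checked PSD)."""
    if len(cov.within_rho) != modules.max() + 1:
        raise ValueError("one within_rho per module is required")
    if not (0.0 <= cov.between_rho <= min(cov.within_rho)):
        raise ValueError(
            f"need 0 <= between_rho <= within_rho, got between={cov.between_rho}, "
            f"within={cov.within_rho}"
        )
    if max(cov.within_rho) >= 1.0:
        raise ValueError(f"within_rho must be < 1, got {cov.within_rho}")
    r = len(modules)
    c = np.full((r, r), cov.between_rho)
    for m, rho in enumerate(cov.within_rho):
        idx = np.flatnonzero(modules == m)
        c[np.ix_(idx, idx)] = rho
    for h in cov.hub_regions:
        outside = modules != modules[h]
        boost = np.maximum(c[h], cov.hub_rho) * outside + c[h] * ~outside
        c[h] = boost
        c[:, h] = boost
    np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError(
            "generating correlation matrix is not positive semi-definite; "
            "parameters must be valid (no nearest-PSD repair)"
        )
    return c


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a two-group synthetic cohort."""

    n_regions: int = 68
    n_modules: int = 4
    n_subjects: tuple[int, int] = (25, 33)
    group_names: tuple[str, str] = ("control", "patient")
    covariance: tuple[GroupCovariance, GroupCovariance] = field(
        default_factory=lambda: (
            GroupCovariance((0.6, 0.667, 0.733, 0.8), 0.1),
            GroupCovariance((0.6, 0.667, 0.733, 0.8), 0.1),
        )
    )
    #: mm per unit of covariate; a scalar applies uniformly across regions,
    #: an array of length n_regions gives region-specific loadings (the
    #: per-region regression model the analysis pipeline assumes)
    covariate_effects: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: {
            "age": -0.008,      # mm per year of age (cortical thinning)
            "gender": 0.03,     # mm offset of the gender=1 coding
            "cirs": -0.004,     # mm per illness-burden point
            "wmh_total": -0.002,  # mm per mL of WMH volume
        }
    )
    base_thickness: float = 2.3  # mm, near typical elderly cortical means
    struct_sd: float = 0.12      # mm, SD of the correlated regional deviation
    noise_sd: float = 0.12       # mm, region-idiosyncratic variation + noise
    wmh_scale: tuple[float, float] = (1.0, 1.0)  # per-group WMH volume scale
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.covariance) != 2 or len(self.n_subjects) != 2:
            raise ValueError("spec describes exactly two groups")
        if min(self.n_subjects) < 3:
            raise ValueError("each group needs >= 3 subjects")
        for cov in self.covariance:
            correlation_matrix(cov, self.modules)  # raises on invalid / non-PSD

    @property
    def modules(self) -> np.ndarray:
        return module_assignment(self.n_regions, self.n_modules)

    @property
    def region_names(self) -> tuple[str, ...]:
        return dk_region_names(self.n_regions)


@dataclass(frozen=True)
class GroundTruth:
    """Generating quantities kept for recovery testing.

    ``correlation`` is the *observable* thickness correlation per group —
    the latent block correlation attenuated by the independent noise,
    ``(struct_sd²·C + noise_sd²·I) / (struct_sd² + noise_sd²)`` — i.e. what
    the empirical association matrix converges to as n grows.
    ``latent_correlation`` is the un-attenuated block matrix C.
    """

    correlation: tuple[np.ndarray, np.ndarray]
    latent_correlation: tuple[np.ndarray, np.ndarray]
    modules: np.ndarray
    covariate_effects: dict[str, float]
    hub_regions: tuple[tuple[int, ...], tuple[int, ...]]
    spec: SyntheticSpec


#: centering points for covariate effects (so base_thickness stays the mean)
_CENTER = {"age": 72.0, "gender": 0.26, "cirs": 5.0, "wmh_total": 7.0}


def _covariates(rng: np.random.Generator, n: int, wmh_scale: float) -> pd.DataFrame:
    # fixed ~26% male fraction (shuffled) so the gender column is never
    # constant within a group, which would make the regression rank-deficient
    gender = np.zeros(n)
    gender[: max(1, round(0.26 * n))] = 1.0
    rng.shuffle(gender)
    return pd.DataFrame(
        {
            "age": rng.uniform(60.0, 84.0, n),
            "gender": gender,
            "cirs": rng.gamma(shape=4.0, scale=1.25, size=n),
            # right-skewed WMH volume with a physiological ceiling (mL)
            "wmh_total": np.minimum(
                rng.lognormal(mean=1.6, sigma=0.9, size=n) * wmh_scale, 80.0
            ),
        }
    )


def generate_cohort(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort from the spec (deterministic under spec.seed).

    Thickness for subject i, region j is
    ``base + Σ_c slope_c (cov_ci − center_c) + struct_sd · z_ij + noise``,
    where z rows are multivariate normal with the group's block correlation
    matrix.  Returns the validated cohort plus the generating ground truth.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    modules = spec.modules
    corrs = tuple(correlation_matrix(c, modules) for c in spec.covariance)
    chols = tuple(np.linalg.cholesky(c + 1e-12 * np.eye(spec.n_regions)) for c in corrs)

    frames, groups, covs = [], [], []
    for g in range(2):
        n = spec.n_subjects[g]
        cov = _covariates(rng, n, spec.wmh_scale[g])
        shift = np.zeros((n, spec.n_regions))
        for name, slope in spec.covariate_effects.items():
            centered = cov[name].to_numpy() - _CENTER.get(name, 0.0)
            slope = np.asarray(slope, dtype=float)
            if slope.ndim == 0:
                shift = shift + slope * centered[:, None]
            elif slope.shape == (spec.n_regions,):
                shift = shift + centered[:, None] * slope[None, :]
            else:
                raise ValueError(
                    f"covariate effect for {name!r} must be scalar or length "
                    f"{spec.n_regions}, got shape {slope.shape}"
                )
        struct = (rng.standard_normal((n, spec.n_regions)) @ chols[g].T) * spec.struct_sd
        noise = rng.standard_normal((n, spec.n_regions)) * spec.noise_sd
        thick = spec.base_thickness + shift + struct + noise
        ids = [f"{spec.group_names[g]}_{i + 1:03d}" for i in range(n)]
        frames.append(pd.DataFrame(thick, index=ids, columns=list(spec.region_names)))
        groups.append(pd.Series(spec.group_names[g], index=ids))
        covs.append(cov.set_index(pd.Index(ids)))

    cohort = CohortTable(
        thickness=pd.concat(frames),
        group=pd.concat(groups),
        covariates=pd.concat(covs),
    )
    a = spec.struct_sd**2 / (spec.struct_sd**2 + spec.noise_sd**2)
    eye = np.eye(spec.n_regions)
    truth = GroundTruth(
        correlation=tuple(a * c + (1 - a) * eye for c in corrs),
        latent_correlation=corrs,
        modules=modules,
        covariate_effects=dict(spec.covariate_effects),
        hub_regions=tuple(c.hub_regions for c in spec.covariance),
        spec=spec,
    )
    return cohort, truth


def plant_segregation_difference(spec: SyntheticSpec, delta_rho: float) -> SyntheticSpec:
    """Raise the second group's within-module correlation by ``delta_rho``.

    At sufficient delta and sample size the pipeline reports higher
    transitivity and modularity for the second group — the qualitative
    segregation signature.  The resulting matrices must remain valid
    (within_rho < 1 and PSD); otherwise construction raises.
    """
    a, b = spec.covariance
    raised = replace(b, within_rho=tuple(w + delta_rho for w in b.within_rho))
    return replace(spec, covariance=(a, raised))


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The standard synthetic cohort (68 regions, 25 vs 33 subjects)."""
    n_modules = overrides.get("n_modules", 4)
    if "covariance" not in overrides and n_modules != 4:
        within = tuple(np.round(np.linspace(0.6, 0.8, n_modules), 3))
        cov = GroupCovariance(within, 0.1)
        overrides["covariance"] = (cov, cov)
    return SyntheticSpec(seed=seed, **overrides)


def null_spec(seed: int = 0, within_rho: float = 0.6, between_rho: float = 0.1, **overrides) -> SyntheticSpec:
    """Identical covariance in both groups with uniform within-module rho.

    The flat-within variant leaves headroom for planting segregation
    differences via :func:`plant_segregation_difference`.
    """
    n_modules = overrides.get("n_modules", 4)
    cov = GroupCovariance((within_rho,) * n_modules, between_rho)
    return SyntheticSpec(seed=seed, covariance=(cov, cov), **overrides)
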