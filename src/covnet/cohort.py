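"""Subject-level cohort tables: reading, validation, and writing.

A cohort table is the raw input of the whole pipeline: one row per subject,
holding regional mean cortical thickness (mm) for a fixed cortical
parcellation, a two-level group label, and numeric nuisance covariates
(age, gender coding, illness burden, optionally white-matter-hyperintensity
volume).  Everything downstream — residualization, correlation networks,
permutation inference — consumes the :class:`CohortTable` produced here, so
validation is strict and region ordering is frozen at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortSchema",
    "CohortTable",
    "read_cohort",
    "write_cohort",
    "read_matrix",
    "write_matrix",
    "MEAN_THICKNESS",
]

#: Canonical name of the derived mean-cortical-thickness covariate.
MEAN_THICKNESS = "mean_thickness"


class CohortError(ValueError):
    """Raised when a cohort table violates the input contract."""


@dataclass(frozen=True)
class CohortSchema:
    """Column mapping for a wide cohort file.

    Parameters
    ----------
    group:
        Name of the column carrying the two-level group label.
    subject:
        Name of the subject-identifier column; defaults to the first column.
    regions:
        Explicit ordered list of region columns.  Mutually exclusive with
        ``region_prefixes``.
    region_prefixes:
        Prefixes identifying region columns (e.g. ``["lh_", "rh_"]``); the
        file's column order is preserved.
    covariates:
        Names of numeric covariate columns to carry along.
    gender_map:
        Optional mapping applied to a non-numeric covariate column (typically
        gender, e.g. ``{"F": 0, "M": 1}``).  The coding is declared here so it
        is explicit and reproducible.
    """

    group: str
    subject: str | None = None
    regions: Sequence[str] | None = None
    region_prefixes: Sequence[str] | None = None
    covariates: Sequence[str] = field(default_factory=tuple)
    gender_map: Mapping[str, float] | None = None

    def region_columns(self, columns: Sequence[str]) -> list[str]:
        if (self.regions is None) == (self.region_prefixes is None):
            raise CohortError(
                "schema must declare exactly one of 'regions' or 'region_prefixes'"
            )
        if self.regions is not None:
            missing = [c for c in self.regions if c not in columns]
            if missing:
                raise CohortError(f"region columns absent from file: {missing}")
            return list(self.regions)
        cols = [
            c
            for c in columns
            if any(c.startswith(p) for p in self.region_prefixes)  # type: ignore[union-attr]
        ]
        if not cols:
            raise CohortError(
                f"no columns match region prefixes {list(self.region_prefixes)}"  # type: ignore[arg-type]
            )
        return cols


@dataclass
class CohortTable:
    """Validated subjects × regions thickness table with covariates.

    Attributes
    ----------
    thickness:
        DataFrame of shape (n_subjects, n_regions), mm; index is the subject
        identifier, columns are region labels in the canonical order used by
        every downstream matrix.
    group:
        Series mapping subject → group label; exactly two levels.
    covariates:
        DataFrame of per-subject numeric covariates (may be empty).
    """

    thickness: pd.DataFrame
    group: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- introspection -----------------------------------------------------

    @property
    def region_names(self) -> list[str]:
        return list(self.thickness.columns)

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]

    @property
    def subjects(self) -> pd.Index:
        return self.thickness.index

    @property
    def group_levels(self) -> list[str]:
        return sorted(pd.unique(self.group).tolist())

    def group_mask(self, level: str) -> np.ndarray:
        return (self.group == level).to_numpy()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        t = self.thickness
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()].tolist()
            raise CohortError(f"duplicate subject identifiers: {dup}")
        if len(set(t.columns)) != t.shape[1]:
            raise CohortError("region names are not unique")
        values = t.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                "thickness must be strictly positive and finite; first offending "
                f"cell: subject {t.index[i]!r}, region {t.columns[j]!r}"
            )
        if not self.group.index.equals(t.index) or not self.covariates.index.equals(
            t.index
        ):
            raise CohortError("group/covariate rows do not match thickness rows")
        levels = self.group_levels
        if len(levels) != 2:
            raise CohortError(f"exactly two group levels required, found {levels}")
        counts = self.group.value_counts()
        small = counts[counts < 3]
        if not small.empty:
            raise CohortError(
                f"each group needs >= 3 subjects (Pearson correlation), got {counts.to_dict()}"
            )
        if not self.covariates.empty:
            nonnum = self.covariates.columns[
                [
                    not np.issubdtype(dt, np.number)
                    for dt in self.covariates.dtypes
                ]
            ].tolist()
            if nonnum:
                raise CohortError(f"non-numeric covariate columns: {nonnum}")

    # -- derived content ---------------------------------------------------

    def ensure_mean_thickness(self) -> "CohortTable":
        """Return a cohort whose covariates include mean cortical thickness.

        If absent, the covariate is the row mean of the thickness matrix (mm).
        """
        if MEAN_THICKNESS in self.covariates.columns:
            return self
        cov = self.covariates.copy()
        cov[MEAN_THICKNESS] = self.thickness.mean(axis=1)
        return replace(self, covariates=cov)

    def with_thickness(self, values: pd.DataFrame, *, validate: bool = False) -> "CohortTable":
        """Return a copy carrying ``values`` in place of the thickness table.

        Used for residual tables, which are mean-zero and therefore exempt
        from the strict-positivity check.
        """
        out = CohortTable.__new__(CohortTable)
        out.thickness = values
        out.group = self.group
        out.covariates = self.covariates
        if validate:
            out.validate()
        return out

    def subset(self, mask: np.ndarray) -> "CohortTable":
        out = CohortTable.__new__(CohortTable)
        out.thickness = self.thickness.loc[mask]
        out.group = self.group.loc[mask]
        out.covariates = self.covariates.loc[mask]
        return out


# -- file I/O ---------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # round_trip parsing + repr writing make read∘write the identity
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _repr_floats(df: pd.DataFrame) -> pd.DataFrame:
    """Format float columns with shortest exact decimal representation."""
    out = df.copy()
    for c in out.columns:
        if np.issubdtype(out[c].dtype, np.floating):
            out[c] = out[c].map(lambda v: repr(float(v)))
    return out


def read_cohort(path: str | Path, schema: CohortSchema) -> CohortTable:
    """Read and validate a wide cohort file (CSV or TSV).

    Region order is the file's column order and is preserved through the
    entire pipeline.  Raises :class:`CohortError` naming the first offending
    subject/region on a missing or non-numeric thickness cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_table(path)
    subject_col = schema.subject or raw.columns[0]
    for col in (subject_col, schema.group):
        if col not in raw.columns:
            raise CohortError(f"required column {col!r} absent from {path.name}")
    raw = raw.set_index(subject_col)

    region_cols = schema.region_columns(list(raw.columns))
    thickness = raw[region_cols].apply(pd.to_numeric, errors="coerce")
    missing = thickness.isna()
    if missing.to_numpy().any():
        i, j = np.argwhere(missing.to_numpy())[0]
        raise CohortError(
            "missing or non-numeric thickness cell: subject "
            f"{thickness.index[i]!r}, region {thickness.columns[j]!r}"
        )

    cov_cols = list(schema.covariates)
    absent = [c for c in cov_cols if c not in raw.columns]
    if absent:
        raise CohortError(f"covariate columns absent from file: {absent}")
    covariates = raw[cov_cols].copy()
    if schema.gender_map is not None:
        for col in covariates.columns:
            if not np.issubdtype(covariates[col].dtype, np.number):
                covariates[col] = covariates[col].map(schema.gender_map)
    covariates = covariates.apply(pd.to_numeric, errors="raise")

    group = raw[schema.group].astype(str)
    if group.nunique() < 2:
        raise CohortError(
            f"group column {schema.group!r} has fewer than 2 levels"
        )
    return CohortTable(thickness=thickness, group=group, covariates=covariates)


def write_cohort(cohort: CohortTable, path: str | Path, *, group_col: str = "group") -> None:
    """Write a cohort as a wide CSV that :func:`read_cohort` can re-read."""
    out = pd.concat(
        [cohort.group.rename(group_col), cohort.covariates, cohort.thickness], axis=1
    )
    out.index.name = out.index.name or "subject_id"
    _repr_floats(out).to_csv(path)


def write_matrix(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write a square labeled matrix as CSV (header row + label column).

    Round-trips bit-identically through :func:`read_matrix` (pandas emits the
    shortest exact decimal representation of each float).
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for a {matrix.shape[0]}x{matrix.shape[0]} matrix"
        )
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    _repr_floats(df).to_csv(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels disagree; not a labeled square matrix")
    return df.to_numpy(dtype=float), list(df.columns)
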