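"""Cohort tables: ingestion, validation, standardization, stratification.

A :class:`CohortTable` is a complete-case subjects-by-variables matrix with
per-row sex and timepoint labels. Networks are always fitted on one stratum
(sex x timepoint); :meth:`CohortTable.stratify` extracts such a sub-table and,
by default, re-standardizes within it, because z-scores computed on the pooled
sample are no longer mean-0/SD-1 after row selection.

Missing values are a hard error throughout — the underlying study design is
complete-case and silent imputation would change every downstream covariance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variables import (
    ROLE_COVARIATE,
    ROLE_METABOLITE,
    VariableSpec,
    validate_schema,
)

SEX_LABELS = ("male", "female")
TIMEPOINT_LABELS = ("baseline", "followup")

#: reserved non-variable columns of the on-disk format
ID_COL, SEX_COL, TIME_COL = "subject_id", "sex", "timepoint"


class CohortSchemaError(ValueError):
    """A required column is absent or the schema itself is malformed."""


class CohortValidationError(ValueError):
    """Cell-level validation failed (missing / non-numeric values, duplicates)."""


class DegenerateVariableError(ValueError):
    """A variable is constant within the table and cannot be standardized."""


@dataclass(frozen=True)
class CohortTable:
    """Subjects x variables matrix with sex/timepoint labels and roles.

    Parameters
    ----------
    values : (n, p) float array of concentrations / covariate values.
    subject_ids, sex, timepoint : per-row labels, length n.
    variables : ordered :class:`VariableSpec` list, length p.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    sex: tuple[str, ...]
    timepoint: tuple[str, ...]
    variables: tuple[VariableSpec, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        for name in ("subject_ids", "sex", "timepoint", "variables"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        validate_schema(self.variables)
        n, p = values.shape
        if not (len(self.subject_ids) == len(self.sex) == len(self.timepoint) == n):
            raise CohortValidationError(
                f"label lengths do not match {n} rows: "
                f"ids={len(self.subject_ids)} sex={len(self.sex)} "
                f"timepoint={len(self.timepoint)}"
            )
        if len(self.variables) != p:
            raise CohortValidationError(
                f"{len(self.variables)} variable specs for {p} columns"
            )
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            r, c = bad[0]
            raise CohortValidationError(
                f"missing or non-numeric value at row {r} "
                f"(variable {self.variables[c].name!r}); no imputation is performed"
            )
        keys = list(zip(self.subject_ids, self.timepoint))
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise CohortValidationError(
                f"duplicate (subject, timepoint) combination {dup}"
            )

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def metabolites(self) -> list[str]:
        return [v.name for v in self.variables if v.role == ROLE_METABOLITE]

    @property
    def covariates(self) -> list[str]:
        return [v.name for v in self.variables if v.role == ROLE_COVARIATE]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, TIME_COL, list(self.timepoint))
        df.insert(0, SEX_COL, list(self.sex))
        df.insert(0, ID_COL, list(self.subject_ids))
        return df

    # -- transformations ---------------------------------------------------
    def standardize(self) -> "CohortTable":
        """Z-score every variable (covariates included) to mean 0, SD 1.

        Sample SD uses the n-1 denominator. Idempotent to numerical
        precision. A constant column raises :class:`DegenerateVariableError`.
        """
        x = self.values
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise DegenerateVariableError(
                f"variable {self.variables[dead[0]].name!r} is constant; "
                "cannot standardize"
            )
        return replace(self, values=(x - mu) / sd)

    def stratify(
        self,
        sex: str | None = None,
        timepoint: str | None = None,
        include_covariates: bool = True,
        restandardize: bool = True,
    ) -> "CohortTable":
        """Select a sex and/or timepoint stratum.

        When ``include_covariates`` is False the covariate columns are dropped
        (unadjusted networks). By default the stratum is re-standardized, so
        the sub-table fed to a network fit is mean-0/SD-1 within itself;
        pass ``restandardize=False`` for pooled standardization semantics.
        """
        mask = np.ones(self.n, dtype=bool)
        if sex is not None:
            found = np.array([s == sex for s in self.sex])
            if not found.any():
                raise CohortValidationError(f"no rows with sex {sex!r}")
            mask &= found
        if timepoint is not None:
            found = np.array([t == timepoint for t in self.timepoint])
            if not found.any():
                raise CohortValidationError(f"no rows with timepoint {timepoint!r}")
            mask &= found
        if not mask.any():
            raise CohortValidationError(
                f"empty stratum sex={sex!r} timepoint={timepoint!r}"
            )
        cols = [
            i
            for i, v in enumerate(self.variables)
            if include_covariates or v.role == ROLE_METABOLITE
        ]
        idx = np.flatnonzero(mask)
        sub = CohortTable(
            values=self.values[np.ix_(idx, cols)],
            subject_ids=[self.subject_ids[i] for i in idx],
            sex=[self.sex[i] for i in idx],
            timepoint=[self.timepoint[i] for i in idx],
            variables=[self.variables[i] for i in cols],
        )
        return sub.standardize() if restandardize else sub


def read_cohort(
    path: str | Path | io.TextIOBase,
    schema: Sequence[VariableSpec],
    sep: str | None = None,
) -> CohortTable:
    """Read a delimited cohort file (CSV/TSV, header row) against a schema.

    Raises :class:`CohortSchemaError` if any schema/label column is missing
    and :class:`CohortValidationError` (citing the row) for missing or
    non-numeric cells. Column order is normalized to schema order.
    """
    validate_schema(schema)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (ID_COL, SEX_COL, TIME_COL):
        if col not in df.columns:
            raise CohortSchemaError(f"required column {col!r} missing from {path}")
    missing = [v.name for v in schema if v.name not in df.columns]
    if missing:
        raise CohortSchemaError(f"schema column(s) missing from {path}: {missing}")
    names = [v.name for v in schema]
    raw = df[names]
    numeric = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        cell = raw.iat[r, c]
        what = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise CohortValidationError(
            f"{what} value in column {names[c]!r} at data row {r}"
        )
    sexes = df[SEX_COL].tolist()
    unknown = sorted(set(sexes) - set(SEX_LABELS))
    if unknown:
        raise CohortValidationError(f"unknown sex label(s) {unknown}")
    return CohortTable(
        values=numeric.to_numpy(dtype=float),
        subject_ids=df[ID_COL].astype(str).tolist(),
        sex=sexes,
        timepoint=df[TIME_COL].tolist(),
        variables=list(schema),
    )


def write_cohort(table: CohortTable, path: str | Path, sep: str = ",") -> None:
    """Write a cohort table in the on-disk delimited format."""
    table.to_frame().to_csv(path, sep=sep, index=False)
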