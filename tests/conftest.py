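"""Shared fixtures: small programmatic cohort tables."""

from __future__ import annotations

import numpy as np
import pytest

from trpnet.cohort import CohortTable
from trpnet.variables import ROLE_COVARIATE, ROLE_METABOLITE, VariableSpec


def make_table(
    values: np.ndarray,
    names: list[str] | None = None,
    sex: str | list[str] = "male",
    timepoint: str | list[str] = "baseline",
    roles: list[str] | None = None,
) -> CohortTable:
    """Wrap a plain matrix in a CohortTable with generated labels."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if names is None:
        names = [f"m{i}" for i in range(p)]
    if roles is None:
        roles = [ROLE_METABOLITE] * p
    sexes = [sex] * n if isinstance(sex, str) else list(sex)
    tps = [timepoint] * n if isinstance(timepoint, str) else list(timepoint)
    return CohortTable(
        values=values,
        subject_ids=[f"s{i:04d}" for i in range(n)],
        sex=sexes,
        timepoint=tps,
        variables=[VariableSpec(nm, r) for nm, r in zip(names, roles)],
    )


def gaussian_table(
    precision: np.ndarray,
    n: int,
    rng: np.random.Generator,
    names: list[str] | None = None,
    standardize: bool = True,
) -> CohortTable:
    """Multivariate-normal draws from inv(precision), optionally z-scored."""
    chol = np.linalg.cholesky(np.linalg.inv(precision))
    table = make_table(rng.standard_normal((n, precision.shape[0])) @ chol.T, names)
    return table.standardize() if standardize else table


def planted_precision(p: int, edges: list[tuple[int, int]], rho: float) -> np.ndarray:
    theta = np.eye(p)
    for i, j in edges:
        theta[i, j] = theta[j, i] = -rho
    assert np.linalg.eigvalsh(theta).min() > 0
    return theta


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def toy_csv(tmp_path):
    """4-row toy cohort CSV: 2 metabolites, 1 covariate, both sexes."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "subject_id,sex,timepoint,m1,m2,c1\n"
        "a,male,baseline,1.0,2.0,3.0\n"
        "b,male,baseline,2.0,1.0,4.0\n"
        "c,female,baseline,3.0,3.0,5.0\n"
        "d,female,baseline,4.0,2.5,6.0\n"
    )
    schema = [
        VariableSpec("m1", ROLE_METABOLITE, "uM"),
        VariableSpec("m2", ROLE_METABOLITE, "uM"),
        VariableSpec("c1", ROLE_COVARIATE, "g"),
    ]
    return path, schema
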