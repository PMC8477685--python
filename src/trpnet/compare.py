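"""Between-group network comparison.

Two tools: a permutation structure-invariance test for GGMs (statistic: the
maximum absolute edge-weight difference between the two groups' selected
networks, the standard network-comparison default) and the Hamming distance
between undirected skeletons for BNs.

The permutation scheme re-runs the FULL estimation pipeline — standardize,
lambda path, IC selection — on each relabeled split, so the null distribution
reflects everything the observed statistic went through. The p-value uses the
add-one correction p = (1 + #{M_perm >= M_obs}) / (1 + n_perm), which keeps
p in (0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import CohortTable
from .edges import EdgeSet
from .ggm import _select_path_from_cov


@dataclass(frozen=True)
class InvarianceResult:
    m_stat: float
    p_value: float
    n_perm: int
    seed: int | None
    per_edge_diffs: np.ndarray
    names: tuple[str, ...]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "m_stat": self.m_stat,
                "p_value": self.p_value,
                "n_perm": self.n_perm,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _pcor_of_split(
    x: np.ndarray, gamma: float, n_points: int, min_ratio: float, tol: float
) -> np.ndarray:
    """Standardize a group's rows and return the IC-selected pcor matrix."""
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # permuted splits may by chance get low-variance columns
    z = (x - x.mean(axis=0)) / sd
    S = (z.T @ z) / (x.shape[0] - 1)
    return _select_path_from_cov(
        S, x.shape[0], gamma=gamma, n_points=n_points, min_ratio=min_ratio, tol=tol
    ).selected.pcor


def invariance_test(
    table_a: CohortTable,
    table_b: CohortTable,
    n_perm: int = 1000,
    seed: int | None = None,
    gamma: float = 0.0,
    n_points: int = 30,
    min_ratio: float = 0.01,
    tol: float = 1e-4,
) -> InvarianceResult:
    """Permutation test of GGM structure equality between two groups.

    Group labels are permuted over the pooled rows (group sizes preserved)
    and both networks refit per permutation. Deterministic under a fixed
    seed. Warns when group sizes are not comparable (ratio > 2), where the
    test's validity degrades.
    """
    if table_a.variable_names != table_b.variable_names:
        raise ValueError(
            "groups must share the same variable set in the same order"
        )
    if table_a.n == 0 or table_b.n == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = table_a.n, table_b.n
    if max(na, nb) > 2 * min(na, nb):
        warnings.warn(
            f"group sizes {na} vs {nb} are not comparable (ratio > 2); "
            "the invariance test may be unreliable",
            stacklevel=2,
        )
    kw = dict(gamma=gamma, n_points=n_points, min_ratio=min_ratio, tol=tol)
    pa = _pcor_of_split(table_a.values, **kw)
    pb = _pcor_of_split(table_b.values, **kw)
    diffs = pa - pb
    p = pa.shape[0]
    iu = np.triu_indices(p, k=1)
    m_obs = float(np.max(np.abs(diffs[iu]))) if p > 1 else 0.0

    pooled = np.vstack([table_a.values, table_b.values])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        qa = _pcor_of_split(pooled[perm[:na]], **kw)
        qb = _pcor_of_split(pooled[perm[na:]], **kw)
        m_perm = float(np.max(np.abs((qa - qb)[iu]))) if p > 1 else 0.0
        if m_perm >= m_obs:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)
    return InvarianceResult(
        m_stat=m_obs,
        p_value=p_value,
        n_perm=n_perm,
        seed=seed,
        per_edge_diffs=diffs,
        names=tuple(table_a.variable_names),
    )


def hamming_distance(a: EdgeSet, b: EdgeSet) -> int:
    """Number of unordered pairs present in exactly one of two skeletons."""
    if a.nodes is not None and b.nodes is not None:
        if set(a.nodes) != set(b.nodes):
            raise ValueError(
                "edge sets are defined over different node vocabularies"
            )
    return len(a.edges ^ b.edges)
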