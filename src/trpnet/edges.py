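"""Undirected edge sets — the common currency of all consensus logic.

Edges are unordered variable-name pairs stored in canonical (lexicographic)
order. Weights are annotations, not identity: a GGM edge carries a signed
partial correlation, a BN edge a bootstrap strength in [0, 1], and a
temporally reproduced edge a (baseline, follow-up) weight pair. Provenance
records which method / sex / timepoint produced the set so that intersections
across incompatible strata can be rejected early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

Pair = tuple[str, str]


def canonical(a: str, b: str) -> Pair:
    """Canonical unordered pair; self-pairs are invalid."""
    if a == b:
        raise ValueError(f"self-pair {a!r}-{b!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Provenance:
    method: str | None = None  # "ggm" | "bn"
    sex: str | None = None
    timepoint: str | None = None
    adjusted: bool | None = None

    def compatible(self, other: "Provenance", fields: Iterable[str]) -> bool:
        return all(
            getattr(self, f) is None
            or getattr(other, f) is None
            or getattr(self, f) == getattr(other, f)
            for f in fields
        )


@dataclass(frozen=True)
class EdgeSet:
    """A set of unordered name pairs with optional weights and provenance."""

    edges: frozenset[Pair]
    weights: Mapping[Pair, object] = field(default_factory=dict)
    provenance: Provenance = field(default_factory=Provenance)
    nodes: tuple[str, ...] | None = None

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]] | Mapping[tuple[str, str], object],
        provenance: Provenance | None = None,
        nodes: Iterable[str] | None = None,
    ) -> "EdgeSet":
        if isinstance(pairs, Mapping):
            weights = {canonical(*k): v for k, v in pairs.items()}
            edges = frozenset(weights)
        else:
            edges = frozenset(canonical(*p) for p in pairs)
            weights = {}
        node_tuple = tuple(nodes) if nodes is not None else None
        if node_tuple is not None:
            known = set(node_tuple)
            stray = [e for e in edges if not known.issuperset(e)]
            if stray:
                raise ValueError(f"edges reference unknown nodes: {sorted(stray)}")
        return cls(
            edges=edges,
            weights=weights,
            provenance=provenance or Provenance(),
            nodes=node_tuple,
        )

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(sorted(self.edges))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical(*pair) in self.edges

    def weight(self, pair: tuple[str, str]):
        return self.weights.get(canonical(*pair))

    @property
    def endpoints(self) -> set[str]:
        return {name for edge in self.edges for name in edge}

    def restrict(self, names: Iterable[str]) -> "EdgeSet":
        """Keep only edges whose BOTH endpoints are in ``names``."""
        keep = set(names)
        edges = frozenset(e for e in self.edges if keep.issuperset(e))
        return EdgeSet(
            edges=edges,
            weights={e: self.weights[e] for e in edges if e in self.weights},
            provenance=self.provenance,
            nodes=self.nodes,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"var_a": a, "var_b": b, "weight": self.weights.get((a, b))}
            for a, b in sorted(self.edges)
        ]
        return pd.DataFrame(rows, columns=["var_a", "var_b", "weight"])
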