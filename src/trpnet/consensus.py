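"""Strong-edge extraction, temporal reproducibility, cross-method consensus.

The headline logic of the analysis: per method and sex, keep only "strong"
edges (|pcor| >= 0.3 for GGMs — the cutoff is on the absolute value, since a
negative -0.31 edge counts as strong; bootstrap strength >= 0.85 for BNs,
both thresholds inclusive), intersect baseline with follow-up to get the
temporally reproducible set, then intersect across the two methods. Edge
identity is the unordered metabolite-name pair only; signs and weights ride
along as annotations, and a GGM sign flip between timepoints is flagged but
does not break reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

from .bn import StrengthTable
from .edges import EdgeSet, Provenance
from .ggm import GGMFit, GGMResults


def possible_pairs(p: int) -> int:
    """Unordered variable pairs: p(p-1)/2. p=19 metabolites -> 171."""
    return p * (p - 1) // 2


def percent(count: int, total: int) -> float:
    """Percentage at one decimal, round-half-up (7/171 -> 4.1, 7/82 -> 8.5)."""
    if total == 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def strong_edges_ggm(
    fit: GGMFit | GGMResults | Mapping[tuple[str, str], float],
    threshold: float = 0.3,
    metabolite_names: Iterable[str] | None = None,
    provenance: Provenance | None = None,
) -> EdgeSet:
    """Edges with |pcor| >= threshold (inclusive), signed weights retained.

    When the fit includes covariate nodes, pass ``metabolite_names`` to
    restrict to metabolite-metabolite pairs (covariate edges are reported
    separately by the pipeline, not fed to consensus).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(fit, GGMResults):
        weights = fit.fit.edge_weights()
    elif isinstance(fit, GGMFit):
        weights = fit.edge_weights()
    else:
        weights = dict(fit)
    strong = {pair: w for pair, w in weights.items() if abs(w) >= threshold}
    es = EdgeSet.from_pairs(strong, provenance=provenance)
    if metabolite_names is not None:
        es = es.restrict(metabolite_names)
    return es


def strong_edges_bn(
    strengths: StrengthTable | Mapping[tuple[str, str], float],
    threshold: float = 0.85,
    metabolite_names: Iterable[str] | None = None,
    provenance: Provenance | None = None,
) -> EdgeSet:
    """Pairs whose bootstrap adjacency frequency is >= threshold (inclusive:
    'appears in at least 85% of resamples')."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    table = strengths.strength if isinstance(strengths, StrengthTable) else strengths
    strong = {pair: s for pair, s in table.items() if s >= threshold}
    es = EdgeSet.from_pairs(strong, provenance=provenance)
    if metabolite_names is not None:
        es = es.restrict(metabolite_names)
    return es


def reproducible_edges(baseline: EdgeSet, followup: EdgeSet) -> EdgeSet:
    """Temporal intersection: edges present at both timepoints.

    Existence-based — signs need not match (flips are recoverable from the
    weights, which become (baseline, followup) pairs). Provenance must agree
    on method, sex and adjustment.
    """
    if not baseline.provenance.compatible(
        followup.provenance, ("method", "sex", "adjusted")
    ):
        raise ValueError(
            f"provenance mismatch: {baseline.provenance} vs {followup.provenance}"
        )
    shared = baseline.edges & followup.edges
    weights = {
        e: (baseline.weights.get(e), followup.weights.get(e)) for e in shared
    }
    prov = Provenance(
        method=baseline.provenance.method or followup.provenance.method,
        sex=baseline.provenance.sex or followup.provenance.sex,
        timepoint=None,
        adjusted=baseline.provenance.adjusted,
    )
    return EdgeSet(edges=frozenset(shared), weights=weights, provenance=prov)


def sign_flips(reproduced: EdgeSet) -> list[tuple[str, str]]:
    """Edges whose GGM pcor changed sign between timepoints."""
    flips = []
    for e, w in reproduced.weights.items():
        if (
            isinstance(w, tuple)
            and all(isinstance(v, (int, float)) and v is not None for v in w)
            and w[0] * w[1] < 0
        ):
            flips.append(e)
    return sorted(flips)


def cross_method_consensus(ggm_rep: EdgeSet, bn_rep: EdgeSet) -> EdgeSet:
    """Edges temporally reproducible under BOTH methods (same sex)."""
    if not ggm_rep.provenance.compatible(bn_rep.provenance, ("sex",)):
        raise ValueError(
            f"sex mismatch: {ggm_rep.provenance.sex} vs {bn_rep.provenance.sex}"
        )
    shared = ggm_rep.edges & bn_rep.edges
    weights = {
        e: {"ggm": ggm_rep.weights.get(e), "bn": bn_rep.weights.get(e)}
        for e in shared
    }
    prov = Provenance(method="consensus", sex=ggm_rep.provenance.sex)
    return EdgeSet(edges=frozenset(shared), weights=weights, provenance=prov)


@dataclass(frozen=True)
class ConsensusReport:
    """Per-sex reproducible and consensus edge sets with report arithmetic."""

    n_metabolites: int
    ggm_reproducible: dict[str, EdgeSet]
    bn_reproducible: dict[str, EdgeSet]
    consensus: dict[str, EdgeSet]
    strong_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    nonzero_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_possible_pairs(self) -> int:
        return possible_pairs(self.n_metabolites)

    @property
    def consensus_counts(self) -> dict[str, int]:
        return {sex: len(es) for sex, es in self.consensus.items()}

    @property
    def overall_consensus_count(self) -> int:
        return sum(self.consensus_counts.values())

    @property
    def metabolite_panel(self) -> tuple[str, ...]:
        names: set[str] = set()
        for es in self.consensus.values():
            names |= es.endpoints
        return tuple(sorted(names))

    @property
    def sign_flips(self) -> dict[str, list[tuple[str, str]]]:
        return {sex: sign_flips(es) for sex, es in self.ggm_reproducible.items()}

    def strong_percent_of_possible(self, sex: str) -> float | None:
        counts = self.strong_counts.get(sex)
        if not counts or "ggm_baseline" not in counts:
            return None
        return percent(counts["ggm_baseline"], self.total_possible_pairs)

    def strong_percent_of_nonzero(self, sex: str) -> float | None:
        counts = self.strong_counts.get(sex)
        if (
            not counts
            or "ggm_baseline" not in counts
            or sex not in self.nonzero_counts
        ):
            return None
        return percent(counts["ggm_baseline"], self.nonzero_counts[sex])

    def to_dict(self) -> dict:
        return {
            "n_metabolites": self.n_metabolites,
            "total_possible_pairs": self.total_possible_pairs,
            "per_sex": {
                sex: {
                    "ggm_reproducible": [list(e) for e in self.ggm_reproducible[sex]],
                    "bn_reproducible": [list(e) for e in self.bn_reproducible[sex]],
                    "consensus": [list(e) for e in self.consensus[sex]],
                    "consensus_count": len(self.consensus[sex]),
                    "sign_flips": [list(e) for e in self.sign_flips[sex]],
                    "strong_counts": self.strong_counts.get(sex, {}),
                    "nonzero_baseline_edges": self.nonzero_counts.get(sex),
                    "strong_pct_of_possible": self.strong_percent_of_possible(sex),
                    "strong_pct_of_nonzero": self.strong_percent_of_nonzero(sex),
                }
                for sex in self.consensus
            },
            "overall_consensus_count": self.overall_consensus_count,
            "metabolite_panel": list(self.metabolite_panel),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def consensus_frame(self):
        import pandas as pd

        rows = []
        for sex in sorted(self.consensus):
            for a, b in self.consensus[sex]:
                rows.append({"sex": sex, "var_a": a, "var_b": b})
        return pd.DataFrame(rows, columns=["sex", "var_a", "var_b"])

    def summary(self) -> str:
        lines = [
            "Consensus of temporally reproducible strong edges",
            f"  metabolites: {self.n_metabolites} "
            f"({self.total_possible_pairs} possible pairs)",
        ]
        for sex in sorted(self.consensus):
            lines.append(
                f"  {sex}: GGM-reproducible {len(self.ggm_reproducible[sex])}, "
                f"BN-reproducible {len(self.bn_reproducible[sex])}, "
                f"consensus {len(self.consensus[sex])}"
            )
            for a, b in self.consensus[sex]:
                lines.append(f"    {a} -- {b}")
        lines.append(
            f"  overall: {self.overall_consensus_count} consensus edges over "
            f"{len(self.metabolite_panel)} metabolites"
        )
        return "\n".join(lines)


def summarize(
    ggm_reproducible: Mapping[str, EdgeSet],
    bn_reproducible: Mapping[str, EdgeSet],
    n_metabolites: int = 19,
    strong_counts: Mapping[str, Mapping[str, int]] | None = None,
    nonzero_counts: Mapping[str, int] | None = None,
) -> ConsensusReport:
    """Assemble the consensus report from per-sex reproducible edge sets.

    Percentages are recomputed from the integer counts (one decimal,
    round-half-up); consensus sets are intersections and therefore subsets
    of every input.
    """
    if set(ggm_reproducible) != set(bn_reproducible):
        raise ValueError("ggm and bn reproducible sets must cover the same sexes")
    consensus = {
        sex: cross_method_consensus(ggm_reproducible[sex], bn_reproducible[sex])
        for sex in ggm_reproducible
    }
    return ConsensusReport(
        n_metabolites=n_metabolites,
        ggm_reproducible=dict(ggm_reproducible),
        bn_reproducible=dict(bn_reproducible),
        consensus=consensus,
        strong_counts={k: dict(v) for k, v in (strong_counts or {}).items()},
        nonzero_counts=dict(nonzero_counts or {}),
    )
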