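"""End-to-end orchestration: config, staged execution, artifacts, replay.

``run_pipeline`` executes, per sex: the unadjusted baseline GGM and BN, the
covariate-adjusted baseline and follow-up GGM and BN, the between-sex
invariance test and BN Hamming distance at baseline, strong-edge extraction,
temporal intersection and cross-method consensus. Artifacts (edge CSVs,
GraphML networks, the consensus report JSON and a run log recording the seed
and every parameter) go to the configured output directory.

Covariate adjustment means covariates enter the networks as ordinary NODES;
consensus logic then filters to metabolite-metabolite pairs, and
covariate-involving strong edges are written to a separate CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bn import GaussianBayesianNetwork
from .cohort import CohortTable, SEX_LABELS, TIMEPOINT_LABELS, read_cohort
from .compare import hamming_distance, invariance_test
from .consensus import (
    ConsensusReport,
    reproducible_edges,
    strong_edges_bn,
    strong_edges_ggm,
    summarize,
)
from .edges import EdgeSet, Provenance
from .ggm import GaussianGraphicalModel
from .variables import default_schema

log = logging.getLogger("trpnet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class GGMParams:
    n_points: int = 100
    min_ratio: float = 0.01
    gamma: float = 0.0
    threshold: float = 0.3
    bootstrap_B: int = 1000
    alpha: float = 0.05


@dataclass
class BNParams:
    B: int = 1000
    threshold: float = 0.85
    restarts: int = 0


@dataclass
class CompareParams:
    n_perm: int = 1000


@dataclass
class PipelineConfig:
    """Full parameterization of a pipeline run.

    The defaults are the canonical analysis settings (strong-edge cutoffs
    0.3 / 0.85, B = 1000 BN bootstraps, 1000 permutations); ``fast()``
    returns a reduced, clearly non-canonical profile for CI-scale runs.
    """

    seed: int = 0
    input: str | None = None
    output_dir: str = "trpnet-output"
    ggm: GGMParams = field(default_factory=GGMParams)
    bn: BNParams = field(default_factory=BNParams)
    compare: CompareParams = field(default_factory=CompareParams)
    profile: str = "canonical"

    def __post_init__(self) -> None:
        if isinstance(self.ggm, dict):
            self.ggm = GGMParams(**self.ggm)
        if isinstance(self.bn, dict):
            self.bn = BNParams(**self.bn)
        if isinstance(self.compare, dict):
            self.compare = CompareParams(**self.compare)
        if not 0 < self.ggm.threshold:
            raise ValueError("ggm.threshold must be > 0")
        if not 0 < self.bn.threshold <= 1:
            raise ValueError("bn.threshold must be in (0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory (stochastic stages)")

    def fast(self) -> "PipelineConfig":
        """Reduced profile (B=100, n_perm=200, 20-point grid) for CI; not
        the canonical analysis settings."""
        cfg = dataclasses.replace(
            self,
            ggm=dataclasses.replace(self.ggm, n_points=20, bootstrap_B=100),
            bn=dataclasses.replace(self.bn, B=100),
            compare=dataclasses.replace(self.compare, n_perm=200),
            profile="fast",
        )
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "input": self.input,
            "output_dir": self.output_dir,
            "ggm": dataclasses.asdict(self.ggm),
            "bn": dataclasses.asdict(self.bn),
            "compare": dataclasses.asdict(self.compare),
            "profile": self.profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls.from_dict(data)


@dataclass(frozen=True)
class PipelineResult:
    report: ConsensusReport
    invariance: dict
    hamming_baseline_bn: int
    artifacts: tuple[str, ...]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(
    config: PipelineConfig, table: CohortTable | None = None
) -> PipelineResult:
    """Execute all stages and write artifacts; any failure aborts with a
    stage-named :class:`PipelineError`."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: list[str] = []
    try:
        log.info("config: %s", json.dumps(config.to_dict()))
        stage = "read input"
        if table is None:
            if config.input is None:
                raise PipelineError("stage 'read input': no input path configured")
            if not Path(config.input).exists():
                raise PipelineError(
                    f"stage 'read input': input file not found: {config.input}"
                )
            table = read_cohort(config.input, default_schema())

        seeds = iter(_subseeds(config.seed, 32))
        ggm_rep: dict[str, EdgeSet] = {}
        bn_rep: dict[str, EdgeSet] = {}
        strong_counts: dict[str, dict[str, int]] = {}
        nonzero_counts: dict[str, int] = {}
        baseline_bn_strong: dict[str, EdgeSet] = {}
        unadjusted_baseline: dict[str, CohortTable] = {}
        covariate_rows: list[dict] = []

        for sex in SEX_LABELS:
            strong_counts[sex] = {}
            # -- unadjusted baseline networks (metabolites only) ----------
            stage = f"unadjusted baseline networks ({sex})"
            stratum = table.stratify(
                sex=sex, timepoint="baseline", include_covariates=False
            )
            unadjusted_baseline[sex] = stratum
            res = GaussianGraphicalModel(stratum).fit(
                gamma=config.ggm.gamma,
                n_points=config.ggm.n_points,
                min_ratio=config.ggm.min_ratio,
            )
            nonzero_counts[sex] = res.edge_count
            strong_counts[sex]["ggm_baseline"] = len(
                strong_edges_ggm(res, config.ggm.threshold)
            )
            _write_ggm(res, out, "ggm_unadjusted", sex, "baseline", artifacts)
            st = GaussianBayesianNetwork(stratum).fit_bootstrap(
                B=config.bn.B, seed=next(seeds)
            )
            baseline_bn_strong[sex] = strong_edges_bn(
                st,
                config.bn.threshold,
                provenance=Provenance("bn", sex, "baseline", adjusted=False),
            )
            st.to_csv(out / f"strengths_bn_unadjusted_{sex}_baseline.csv")
            artifacts.append(f"strengths_bn_unadjusted_{sex}_baseline.csv")

            # -- adjusted networks at both timepoints ----------------------
            per_tp_ggm: dict[str, EdgeSet] = {}
            per_tp_bn: dict[str, EdgeSet] = {}
            for tp in TIMEPOINT_LABELS:
                stage = f"adjusted {tp} networks ({sex})"
                stratum = table.stratify(
                    sex=sex, timepoint=tp, include_covariates=True
                )
                metabolites = stratum.metabolites
                res = GaussianGraphicalModel(stratum).fit(
                    gamma=config.ggm.gamma,
                    n_points=config.ggm.n_points,
                    min_ratio=config.ggm.min_ratio,
                )
                prov = Provenance("ggm", sex, tp, adjusted=True)
                all_strong = strong_edges_ggm(
                    res, config.ggm.threshold, provenance=prov
                )
                per_tp_ggm[tp] = all_strong.restrict(metabolites)
                for a, b in sorted(all_strong.edges - per_tp_ggm[tp].edges):
                    covariate_rows.append(
                        {
                            "method": "ggm",
                            "sex": sex,
                            "timepoint": tp,
                            "var_a": a,
                            "var_b": b,
                            "weight": all_strong.weights.get((a, b)),
                        }
                    )
                _write_ggm(res, out, "ggm_adjusted", sex, tp, artifacts)
                st = GaussianBayesianNetwork(stratum).fit_bootstrap(
                    B=config.bn.B, seed=next(seeds)
                )
                prov = Provenance("bn", sex, tp, adjusted=True)
                bn_strong = strong_edges_bn(
                    st, config.bn.threshold, provenance=prov
                )
                per_tp_bn[tp] = bn_strong.restrict(metabolites)
                for a, b in sorted(bn_strong.edges - per_tp_bn[tp].edges):
                    covariate_rows.append(
                        {
                            "method": "bn",
                            "sex": sex,
                            "timepoint": tp,
                            "var_a": a,
                            "var_b": b,
                            "weight": bn_strong.weights.get((a, b)),
                        }
                    )
                st.to_csv(out / f"strengths_bn_adjusted_{sex}_{tp}.csv")
                artifacts.append(f"strengths_bn_adjusted_{sex}_{tp}.csv")
                strong_counts[sex][f"ggm_adjusted_{tp}"] = len(per_tp_ggm[tp])
                strong_counts[sex][f"bn_adjusted_{tp}"] = len(per_tp_bn[tp])

            stage = f"temporal intersection ({sex})"
            ggm_rep[sex] = reproducible_edges(
                per_tp_ggm["baseline"], per_tp_ggm["followup"]
            )
            bn_rep[sex] = reproducible_edges(
                per_tp_bn["baseline"], per_tp_bn["followup"]
            )

        stage = "between-sex comparison at baseline"
        inv = invariance_test(
            unadjusted_baseline["male"],
            unadjusted_baseline["female"],
            n_perm=config.compare.n_perm,
            seed=next(seeds),
            gamma=config.ggm.gamma,
            n_points=min(config.ggm.n_points, 30),
            min_ratio=config.ggm.min_ratio,
        )
        inv.to_json(out / "invariance_baseline.json")
        artifacts.append("invariance_baseline.json")
        hamming = hamming_distance(
            baseline_bn_strong["male"], baseline_bn_strong["female"]
        )

        stage = "consensus report"
        report = summarize(
            ggm_rep,
            bn_rep,
            n_metabolites=len(table.metabolites),
            strong_counts=strong_counts,
            nonzero_counts=nonzero_counts,
        )
        report.consensus_frame().to_csv(out / "consensus_edges.csv", index=False)
        artifacts.append("consensus_edges.csv")
        if covariate_rows:
            import pandas as pd

            pd.DataFrame(covariate_rows).to_csv(
                out / "covariate_strong_edges.csv", index=False
            )
            artifacts.append("covariate_strong_edges.csv")
        payload = {
            "config": config.to_dict(),
            "report": report.to_dict(),
            "invariance": {
                "m_stat": inv.m_stat,
                "p_value": inv.p_value,
                "n_perm": inv.n_perm,
            },
            "hamming_baseline_bn": hamming,
        }
        (out / "consensus_report.json").write_text(json.dumps(payload, indent=2))
        artifacts.append("consensus_report.json")
        log.info("completed; artifacts: %s", artifacts)
        return PipelineResult(
            report=report,
            invariance=payload["invariance"],
            hamming_baseline_bn=hamming,
            artifacts=tuple(artifacts),
        )
    except PipelineError:
        raise
    except Exception as exc:
        log.error("failed at stage %r: %s (partial artifacts: %s)", stage, exc, artifacts)
        raise PipelineError(
            f"stage {stage!r} failed: {exc} (partial artifacts flagged: {artifacts})"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_ggm(res, out: Path, tag: str, sex: str, tp: str, artifacts: list[str]):
    res.to_edge_csv(out / f"edges_{tag}_{sex}_{tp}.csv")
    res.to_graphml(out / f"network_{tag}_{sex}_{tp}.graphml")
    artifacts += [f"edges_{tag}_{sex}_{tp}.csv", f"network_{tag}_{sex}_{tp}.graphml"]


@dataclass(frozen=True)
class ReplayResult:
    ok: bool
    message: str
    differing_edges: tuple[str, ...] = ()


def replay(report_path: str | Path, table: CohortTable | None = None) -> ReplayResult:
    """Re-run a recorded pipeline with its stored seed and verify that the
    consensus edge set (JSON and CSV artifact) is reproduced exactly."""
    report_path = Path(report_path)
    payload = json.loads(report_path.read_text())
    config = PipelineConfig.from_dict(payload["config"])
    recorded: set[tuple[str, str, str]] = set()
    for sex, block in payload["report"]["per_sex"].items():
        for a, b in block["consensus"]:
            recorded.add((sex, a, b))
    # the stored CSV must agree with the stored JSON (detects edited artifacts)
    csv_path = report_path.parent / "consensus_edges.csv"
    if csv_path.exists():
        import pandas as pd

        stored = {
            (r.sex, r.var_a, r.var_b)
            for r in pd.read_csv(csv_path).itertuples()
        }
        if stored != recorded:
            diff = sorted(
                "/".join(t) for t in stored.symmetric_difference(recorded)
            )
            return ReplayResult(
                False, f"consensus CSV disagrees with report JSON: {diff}", tuple(diff)
            )
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        rerun_cfg = dataclasses.replace(config, output_dir=tmp)
        result = run_pipeline(rerun_cfg, table=table)
    rerun: set[tuple[str, str, str]] = set()
    for sex, es in result.report.consensus.items():
        for a, b in es:
            rerun.add((sex, a, b))
    if rerun == recorded:
        return ReplayResult(True, "consensus edge set reproduced exactly")
    diff = sorted("/".join(t) for t in rerun.symmetric_difference(recorded))
    return ReplayResult(
        False, f"reproducibility failure; differing edges: {diff}", tuple(diff)
    )
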