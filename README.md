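# trpnet

Sex-stratified metabolite network analysis with two complementary methods —
regularized partial-correlation networks (Gaussian graphical models) and
linear-Gaussian Bayesian networks — plus the consensus logic that extracts
**strong, temporally reproducible** metabolite associations shared by both.

The package was built around urinary tryptophan metabolomics in adolescent
cohorts (tryptophan and 18 downstream catabolites of the kynurenine,
serotonin and indole pathways, measured at two timepoints one year apart),
but the machinery is generic: any wide-format cohort table with per-row sex
and timepoint labels works. It is intended for epidemiologists and systems
biologists who want reproducible, seedable network pipelines rather than
one-off scripts.

## The models

**Gaussian graphical model (GGM).** For standardized concentrations with
sample covariance S, the graphical lasso estimates a sparse precision matrix

    Θ̂ = argmax_{Θ≻0}  log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|

and edges are the nonzero regularized partial correlations
ρ̂_ij = −Θ̂_ij / √(Θ̂_ii Θ̂_jj). The penalty λ is chosen on a descending
log-spaced grid by the (extended) Bayesian information criterion
IC(λ) = −2ℓ(Θ̂) + E·log n + 4γE·log p (γ = 0, plain BIC, by default).
Edges with |ρ̂| ≥ 0.3 count as *strong*.

**Bayesian network (BN).** Structures are learned by greedy BIC hill
climbing over DAGs (linear-Gaussian local scores), repeated on B = 1000
bootstrap row-resamples. The *strength* of an unordered pair is the fraction
of resamples whose learned DAG contains it in either direction; pairs with
strength ≥ 0.85 count as strong. Directions are learned but deliberately not
interpreted.

**Consensus.** Per sex and method, strong edges present at both timepoints
are *temporally reproducible*; the per-sex consensus is the intersection of
the GGM-reproducible and BN-reproducible sets. Between-sex differences are
assessed with a permutation network-structure invariance test (statistic:
maximum absolute edge-weight difference) and the Hamming distance between BN
skeletons.

A synthetic cohort generator (`trpnet.synthetic`) plants sparse precision
structures with stable/unstable edges and emulates the study design
(64 males + 68 females, two timepoints, right-skewed concentration scales,
correlated covariate pairs), so the whole pipeline is testable without the
non-public cohort data.

## Worked example: the published edge lists

The package ships the published strong-edge lists of the DONALD tryptophan
network analysis (`trpnet.published`) — enough input to run the entire
consensus layer:

```python
from trpnet import published as pub
from trpnet.consensus import reproducible_edges, summarize

ggm_rep, bn_rep = {}, {}
for sex in ("male", "female"):
    ggm_rep[sex] = reproducible_edges(
        pub.ggm_strong_edges(sex, "baseline"), pub.ggm_strong_edges(sex, "followup"))
    bn_rep[sex] = reproducible_edges(
        pub.bn_strong_edges(sex, "baseline"), pub.bn_strong_edges(sex, "followup"))

report = summarize(
    ggm_rep, bn_rep, n_metabolites=19,
    strong_counts={s: {"ggm_baseline": pub.BASELINE_STRONG_EDGES[s]} for s in ggm_rep},
    nonzero_counts=pub.BASELINE_NONZERO_EDGES)
print(report.summary())
```

prints

```
Consensus of temporally reproducible strong edges
  metabolites: 19 (171 possible pairs)
  female: GGM-reproducible 3, BN-reproducible 7, consensus 3
    3-hydroxyanthranilic-acid -- 3-hydroxykynurenine
    3-hydroxykynurenine -- kynurenine
    indole-3-acetic-acid -- kynurenic-acid
  male: GGM-reproducible 3, BN-reproducible 2, consensus 2
    kynurenic-acid -- xanthurenic-acid
    kynurenine -- tryptophan
  overall: 5 consensus edges over 7 metabolites
```

Five associations survive both methods and both timepoints: two in males
(tryptophan–kynurenine, kynurenic acid–xanthurenic acid) and three in
females (kynurenine–3-hydroxykynurenine, 3-hydroxykynurenine–
3-hydroxyanthranilic acid, kynurenic acid–indole-3-acetic acid), spanning a
seven-metabolite panel. `report.strong_percent_of_possible("male")` gives
4.1 (% of the 171 possible pairs that were strong at baseline) and
`report.strong_percent_of_nonzero("male")` gives 8.5 (% of the 82 nonzero
baseline edges).

## Fitting your own data

```python
from trpnet import (GaussianGraphicalModel, GaussianBayesianNetwork,
                    read_cohort, default_schema)

table = read_cohort("cohort.csv", default_schema())
stratum = table.stratify(sex="female", timepoint="baseline",
                         include_covariates=False)

ggm = GaussianGraphicalModel(stratum).fit()     # lambda path + BIC selection
print(ggm.summary())                            # selected lambda, edge list
bn = GaussianBayesianNetwork(stratum)
strengths = bn.fit_bootstrap(B=1000, seed=1)    # bootstrap strength table
```

or run everything (all strata, both methods, comparison tests, consensus,
artifact files) from a shell:

```sh
trpnet simulate --preset donald-like --seed 7 -o data/
trpnet run --config config.yaml            # add --fast for a reduced profile
trpnet replay --report out/consensus_report.json
```

`replay` re-runs a recorded analysis with its stored seed and verifies the
consensus edge set is reproduced exactly.

## Acceptance script

`scripts/acceptance.py` exercises the full pipeline end to end: it generates
a DONALD-like synthetic cohort (19 metabolites on realistic concentration
scales, 5 covariates, 64/68 subjects, two timepoints, planted stable and
unstable edges), runs both network arms per sex with strong-edge extraction,
temporal intersection, cross-method consensus and the between-sex tests, and
prints the resulting consensus report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
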