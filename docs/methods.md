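# Methods

This note documents the statistical procedures implemented in `trpnet`, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish.

## Data model and preprocessing

The unit of analysis is a complete-case cohort table: one row per subject
per timepoint, 19 metabolite concentrations (µM) and 5 covariates (birth
weight g, birth length cm, BMI kg/m², energy kcal/day, protein g/day), with
sex ∈ {male, female} and timepoint ∈ {baseline, followup} labels. Missing or
non-numeric cells are a hard error — no imputation, ever — because every
downstream quantity is a covariance functional and silent imputation would
bias it invisibly.

All variables, covariates included, are z-scored to mean 0 and SD 1 (sample
SD, n−1 denominator; this matters because the z-scores feed covariance
estimates). **Standardization scope:** z-scores are recomputed within each
analysis stratum (the sex × timepoint sub-table actually fed to a network
fit), since networks are fitted per stratum and pooled z-scores are no
longer mean-0/SD-1 after row selection. Pooled standardization is available
(`stratify(..., restandardize=False)`) for sensitivity analyses; whether the
original analysis standardized per stratum or pooled is not determinable,
and per-stratum is the default here.

Covariate adjustment means covariates enter the networks as ordinary
*nodes* (no structural constraints), after which consensus logic keeps only
metabolite–metabolite pairs; covariate-involving strong edges (e.g. birth
weight–birth length) are written to a separate artifact. This nodes-based
reading is forced by the fact that covariate–covariate edges are reported
*inside* the adjusted networks.

## Gaussian graphical model arm

The graphical lasso maximizes `log det Θ − tr(SΘ) − λ Σ_{i≠j}|Θ_ij|` over
positive-definite precision matrices. Conventions:

- **Penalty on off-diagonal entries only** (diagonal unpenalized), matching
  common regularized-partial-correlation practice; `penalize_diagonal=True`
  is available.
- **Solver:** Friedman-style block coordinate descent over columns of the
  working covariance W, inner lasso sub-problems by coordinate descent.
  Stopping rule: duality gap `|tr(SΘ) − p + λ‖Θ‖₁,off| < tol`, default
  `tol = 1e-4`, `max_iter = 200` (exceeding it raises, carrying the last
  gap). The solver is in-package because the pipeline refits the entire λ
  path inside bootstrap and permutation loops (10⁴–10⁵ refits at small p);
  generic library solvers carry per-call overhead that dominates there. The
  sklearn implementation is the independent cross-check in the test suite:
  penalized objectives agree to ~1e-3 and solutions to solver precision
  (~1e-3 entrywise at the default gap tolerance).
- **λ = 0** is solved by direct inversion (error advising λ > 0 when S is
  singular). **Exact zeros:** post-convergence entries with |Θ_ij| < 1e-10
  are structural zeros; λ ≥ max_{i≠j}|S_ij| yields the exactly-empty network
  (a property of the soft-threshold updates, asserted in tests).
- **Grid:** 100 log-spaced values from λ_max = max|S_ij| down to
  0.01·λ_max (both counts configurable). A diagonal S degenerates to the
  single-point grid {0} with a warning.
- **Selection:** IC(λ) = −2ℓ(Θ̂) + E log n + 4γE log p with
  ℓ = (n/2)(log det Θ − tr(SΘ)) − (np/2)log 2π and E the edge count.
  Default γ = 0 (plain BIC — the criterion the source analysis names);
  γ = 0.5 is exposed because common tooling defaults differ, and runs log
  the choice. Ties select the larger λ (sparser fit). A λ whose fit fails
  is dropped with a logged warning.

**Strong edges:** |ρ̂| ≥ 0.3, inclusive, on the *absolute* partial
correlation — the reported strong sets include a −.31 edge, so the cutoff
cannot be one-sided. An edge at exactly 0.30 is retained.

**Connection difference test:** B ≥ 100 nonparametric row-resamples (at the
original n) refit the IC-selected GGM; for each pair of original edges the
percentile (1−α) interval of ρ̂_e1 − ρ̂_e2 is computed, and the pair differs
significantly when the interval excludes 0. Resamples are re-standardized
before refitting. Deterministic given a seed.

## Bayesian network arm

Linear-Gaussian DAGs scored by decomposable BIC: per node,
`loglik_ML(v ~ parents) − (|parents|+2)/2 · log n`, counting coefficients +
intercept + variance (the intercept is ≈0 on standardized data but is still
counted — stated so bootstrap runs are exactly reproducible across
implementations). Local scores come from the centered Gram matrix, making a
hill climb O(moves·|Pa|³) after one O(np²) pass; a 1000-fold bootstrap at
p ≈ 20 costs seconds, not hours.

Hill climbing starts from the empty graph and applies the best-scoring
single arc addition/deletion/reversal until no move improves. Tie-breaks are
deterministic lexicographic on (operation, parent, child), so B = 1000 runs
reproduce bit-for-bit under a fixed seed. Plain hill climbing (no tabu, no
restarts) is the default — the canonical procedure — with seeded random
restarts available. **Known limitation:** greedy search guarantees a local
optimum only; on dense collider-rich structures it can provably miss the
global BIC optimum even when no single move improves (verified against
exhaustive 543-DAG enumeration in the tests). With restarts it reaches the
enumeration optimum on all test panels.

Bootstrap strengths aggregate *adjacency* frequency — direction is ignored,
because only undirected strength is interpreted (moderate n makes learned
orientations unreliable). Direction fractions are computed and stored in the
strength tables but feed nothing downstream. Strong pairs: strength ≥ 0.85,
inclusive ("at least 85% of resamples").

## Between-group comparison

- **Invariance test:** statistic M = max_{i<j} |ρ̂^A_ij − ρ̂^B_ij| between
  the two groups' IC-selected GGMs (the standard network-comparison
  default; the source names only the test). Group labels are permuted over
  pooled rows preserving group sizes, and the *full* estimation pipeline
  (standardize → λ path → IC selection) is re-run per permuted group.
  p = (1 + #{M_perm ≥ M_obs}) / (1 + n_perm) ∈ (0, 1]. Default
  n_perm = 1000. The test warns when group sizes differ by more than 2:1.
  Note the statistic is degenerate when both groups select empty networks
  (M = 0 ties everywhere, p = 1); calibration claims apply to settings with
  shared non-trivial structure.
- **Hamming distance** between undirected skeletons: |symmetric difference|
  of the unordered pair sets, defined only over a common node vocabulary.
  The originally reported distance of 13 between full baseline BNs is not
  recomputable without the raw data and is not a test target.

## Consensus layer

Edge identity is the canonical unordered name pair; weights and signs are
annotations. Temporal reproducibility is existence-based intersection —
a sign flip between timepoints is *flagged* but does not break
reproducibility (weights become (baseline, followup) pairs). Cross-method
consensus intersects the GGM- and BN-reproducible sets per sex. Report
percentages are recomputed from integer counts at one decimal, round-half-up
(7/171 → 4.1, 4/171 → 2.3, 7/82 → 8.5). The reported female figure "4
(5.5%)" is arithmetically inconsistent with 4/76 (5.3%); the report computes
from counts and makes no attempt to match it.

## Synthetic cohort generator

The generator states a fixed world: n = 64 males + 68 females (defaults),
two timepoints per subject, 19 metabolites, 5 covariates with planted pair
correlations r = 0.7 (birth weight–length) and r = 0.8 (energy–protein) —
values chosen once to represent the "strong, consistent" covariate coupling
described for such cohorts. Metabolite dependence is planted through a
per-timepoint precision matrix Θ*: unit diagonal, −ρ at planted edges
(default target ρ = 0.5), edges preferentially chosen as a matching so the
planted partial correlation *equals* the target exactly; positive
definiteness and planted |pcor| ≥ min(0.4, target) are verified by direct
computation, and an infeasible edge budget raises. Stable edges appear in
both timepoints' Θ*, unstable edges in exactly one. Both analysis arms
share this single ground truth: the BN view is an acyclic orientation of
the planted edge set (unions of paths moralize to their own skeleton).

Marginals: `gaussian` mode (unit-test default) emits the latent multivariate
normal directly, since the pipeline standardizes anyway. `realistic` mode
maps each metabolite through a monotone log-normal quantile transform onto
the study-scale medians/IQRs (µM) and covariates onto their natural units;
monotone maps preserve the latent rank correlations (property-tested). Two
scale entries are not from the source tables: 3-hydroxykynurenine's lower
quartile is floored at median/10 (the printed q25 is 0, impossible for a
log-normal), and 5-hydroxytryptophan — absent from the printed
characteristics table — carries a synthetic stand-in on the serotonin scale.

What a green recovery test establishes: with 2 planted stable edges at
|pcor| = 0.5 and n = 150/sex, the full dual-method pipeline recovers both in
≥ 80% of seeds and essentially never promotes single-timepoint edges. What
it does not establish: behavior under real urine-metabolomics features —
measurement error, creatinine/volume variation, batch effects, non-Gaussian
tail dependence — none of which the generator emulates. At the study's own
n = 64/68, GGM shrinkage routinely pulls planted |ρ̂| below the 0.3 cutoff;
a null consensus at that size is expected generator behavior, not a bug.

## Numerical and reproducibility choices

- Every stochastic stage (bootstraps, permutations, simulation) takes an
  integer seed; the pipeline derives stage seeds from one master seed via
  `SeedSequence`, all below 2³¹. Same config + seed ⇒ byte-identical
  consensus CSV (tested).
- BN bootstrap resamples are *not* re-standardized (centering happens inside
  the Gram scorer; column scale shifts all structures' likelihoods almost
  equally), while GGM bootstrap resamples *are* (the pcor threshold is
  scale-sensitive). Degenerate permuted splits guard zero SDs by treating
  the column as unit-scale.
- ML variance in node scores is floored at 1e-300 to survive exact fits;
  parent sets with |Pa| + 2 ≥ n or collinear parents raise a
  rank-deficiency error.
- Hill-climb moves require improvement > 1e-10 (guards float-tie cycling);
  glasso structural zeros use the 1e-10 threshold.

## Limitations

- The graphical-lasso solver targets a 1e-4 duality gap; entrywise solution
  precision is ~1e-3, adequate for a 0.3 edge threshold but not for
  high-precision precision-matrix recovery.
- Arc directionality is computed but intentionally uninterpreted; no
  dynamic (inter-timepoint) models; no mixed/discrete networks; no
  nonparanormal transforms; no centrality analysis.
- The invariance test inherits the usual permutation-test caveats under
  strong group-size imbalance and heavy-tailed marginals.
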