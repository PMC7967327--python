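# Methods

## The procedure

`riskrules` analyzes case–control genotypes for a candidate panel of risk
variants in five stages.

1. **Encoding.** Genotypes are risk-allele counts (0/1/2, with missing
   codes). Residual missingness is imputed — by default with the variant's
   modal code (deterministic), optionally with an iterative random-forest
   scheme that re-predicts each incomplete variant from all others until
   assignments stabilize. Counts are then collapsed to one binary item per
   variant under the dominant model: *presence* items are true for carriers
   of ≥1 risk allele; *absence* items (for protective alleles whose absence
   confers risk) are true at zero copies. The disease indicator is appended
   as the single phenotype item. Complement ("no risk allele") items are
   deliberately not generated.

2. **Mining.** Apriori frequent-itemset search over the incidence matrix
   with exact bitset counting, followed by rule generation restricted to
   the disease consequent: each frequent itemset containing the disease
   item yields the one candidate rule (itemset ∖ {D}) → D, kept when
   confidence ≥ the threshold. Defaults mirror the study design this
   package emulates: support ≥ 0.05, confidence ≥ 0.80, rule length
   (|LHS| + 1) ≤ 5. The production path (`mine_rules`) exploits the fixed
   consequent: count(S ∪ {D}) equals the count of S among subjects with D,
   so itemsets are mined on the case-conditioned submatrix with an absolute
   count threshold relative to the full cohort. This is exactly equivalent
   to the generic path (`frequent_itemsets` + `generate_rules`) — a
   property test checks both against exhaustive enumeration — but prunes
   much harder. A configurable candidate cap (default 5 × 10⁶) refuses
   degenerate threshold choices instead of exhausting memory.

3. **Association.** Each rule's carrier indicator is tested against the
   phenotype in a logistic model adjusted for the leading substructure
   coordinates (default 3). Substructure coordinates are classical MDS
   (principal coordinates) of the pairwise identity-by-state distance
   1 − (proportion of alleles shared), sign-fixed so the largest-magnitude
   loading is positive. Inference is by subject-resampling bootstrap
   (default 5000 replicates, unstratified; a case/control-stratified option
   exists): the point estimate is always the full-data fit, the SE is the
   replicate standard deviation, the CI is a bias-corrected (BC) percentile
   interval, and the p-value is two-sided normal from point/SE. Replicates
   that fail to converge are dropped and counted; >10% drops flags the
   result unstable. Bonferroni correction (α/m over the m tested rules)
   flags the family-wise survivors.

4. **Interaction decomposition** for a three-variant rule: odds ratios of
   each of the 8 carrier profiles against the (0,0,0) reference (Haldane
   +0.5 on zero cells, always flagged; empty strata are reported as
   undefined, never silently corrected), the three-way excess-odds
   decomposition RERI₃ = OR₁₁₁ − OR₁₁₀ − OR₁₀₁ − OR₀₁₁ + OR₁₀₀ + OR₀₁₀ +
   OR₀₀₁ − 1 and AP₃ = RERI₃/OR₁₁₁ with a two-sided percentile bootstrap p
   for AP₃, and the fully parameterized multiplicative model (all main
   effects, all two-way products, the three-way product, covariates) whose
   exponentiated three-way coefficient and Wald p are reported. AP₃ ≤ 1
   always, and AP₃ = 0 exactly when RERI₃ = 0.

5. **Summaries.** Deterministic rule ranking (descending key, ties by
   higher support then lexicographic LHS), per-item membership counts over
   all rules and over the top-k by confidence, dyad co-occurrence
   (conditional and joint percentages; the conditional is *undefined*, not
   0, for an item in no rules), a bipartite item → rule network (GraphML;
   rule-node size attribute = support), and exact-integer binomial
   search-space counts.

## Logistic fitter

The logistic fitter is IRLS (Newton scoring) with a 1e-8 log-likelihood
convergence tolerance and a 100-iteration cap. The design matrix is checked
for full column rank up front (pivoted QR; collinear columns are named in
the error). Complete/quasi-complete separation is detected by diverging
coefficient magnitude (|β| > 15) and flagged; a Firth-penalized fit
(Jeffreys prior) is available as a labeled fallback for separated
interaction models. The fitter agrees with an independent reference
implementation to 1e-6 on coefficients in the test suite, and a
single-binary-predictor fit reproduces the crude odds ratio exactly.

Crude 2×2 odds ratios use ad/bc with Woolf log-scale intervals; zero cells
get the Haldane +0.5 correction only when requested, and always with a
visible flag — with correction disabled, an infinite/zero OR is returned
flagged rather than silently adjusted.

## Synthetic cohort generator

The generator emulates a modestly sized candidate-variant case–control
study: n_cases = 207, n_controls = 179, 196 biallelic variants.

- **Genotypes**: Hardy–Weinberg draws at per-variant MAFs sampled uniformly
  from (0.05, 0.22). The ceiling matters: it controls dominant-carrier
  frequencies and therefore how many chance itemsets clear the support
  threshold. This range reproduces the rule profile the design targets —
  on the order of 10²  mined rules, essentially all with three-variant
  LHS, with planted-pattern carrier counts of ~20–30 of 386 — mirroring a
  study whose rules all had length 4 with support 0.052–0.104.
- **Planted patterns**: a pattern is 2–4 variant ids, a joint odds ratio
  applied when a subject carries ≥1 risk allele at *every* item, and weak
  per-item marginal odds ratios (default 1.1). Pattern items' MAF is pinned
  (default 0.20) so the planted pattern is frequent enough to be minable.
  Defaults plant two triads, joint OR 20 and 8.
- **Disease**: logistic liability — logit(prevalence) + Σ marginal
  log-ORs·carrier + joint log-OR·all-carried + substructure term. Baseline
  prevalence 0.2; subjects are drawn in batches and the first n_cases
  cases / n_controls controls retained, so group sizes are exact
  (in-sample prevalence 207/386 ≈ 0.54). An infeasible demand fails at the
  oversampling cap naming the short group. Controls are assumed to be
  disease-free draws from the same base population.
- **Substructure**: a latent two-group mixture; each variant's MAF is
  shifted ±0.05 in group 2, and the group adds ±substructure_effect/2
  (default 0.3) to the liability. Returned covariates are the true group
  indicator plus Gaussian noise (σ = 0.25) — enough to exercise covariate
  adjustment without population-genetic realism.
- **Missingness**: a small subset of variants (default 7) receives
  independent missingness at the configured rate (≤ 5%; default run uses
  1.3%).

One integer seed drives all randomness through a single named generator;
identical seed + config is bit-identical output.

What the generator does **not** model: linkage disequilibrium or other
inter-variant correlation, X-linked or sex-specific effects, genotyping
error, or realistic ancestry structure. Passing tests therefore demonstrate
correctness of the machinery and behavior under idealized independence —
not performance on LD-structured real panels, where the effective number of
independent itemsets is smaller.

## Calibrations frozen in the test suite

All Monte-Carlo expectations were computed from the generative model before
being frozen as regression tests.

- **Realized planted effect.** A single OR = 20 triad with unit marginals:
  the median realized crude OR across 100 seeds is ≈ 24 (IQR ≈ 14–47); the
  upward shift versus 20 comes from the Haldane correction at ~0–2 control
  carriers. Frozen band on the 100-seed median: [12, 45].
- **Null planted effect.** With joint OR = 1 the median triad-carrier OR
  across seeds is ≈ 1.02; frozen band [0.6, 1.5].
- **Recovery.** A planted OR = 20 triad at n = 386 was mined in 40/40
  calibration seeds and was the top-confidence rule in 22/40 (a majority).
  The frozen regression runs seeds 0–11: all mined, ≥ 7/12 top-ranked.
- **Bootstrap coverage.** BC 95% intervals at a planted dyad OR of 5 with
  well-populated cells cover the truth in 138/150 fixed seeds (92.0%),
  within the binomial 95% band around 0.95 at n = 150. With sparse cells
  (expected control-carrier count ~5) coverage drops to ≈ 89% — the
  familiar small-cell behavior of delta-method/bootstrap SEs, which is why
  the coverage experiment uses a dyad design.

## Post-selection inference: a real limitation

Bonferroni over the *mined* rule family does not control the family-wise
error over the full search space. Under a global null at study scale, the
generator's cohorts still yield a median of ~18 (no substructure) to ~31
(with substructure) chance rules with confidence ≥ 0.80 out of ~1.2 × 10⁶
candidate triples, and in ≥ 80% of null cohorts at least one of them
survives Bonferroni within its own small family — with either Wald or
bootstrap p-values. This mirrors the screening-then-testing structure of
the emulated design itself (where only a minority of mined rules survived
correction) and is intrinsic to conditioning the tested family on the
mining step. Mined-rule p-values should be read as descriptive rankings;
confirmation requires an independent cohort. The test suite freezes the
measured chance-rule behavior as a regression rather than asserting a
nominal error rate the procedure cannot deliver.

## Numerical and design choices

- Rule length counts LHS + RHS, so "lengths 2–5" means 1–4 LHS variants.
- Only disease-consequent rules are generated; variant → variant rules are
  out of scope, as are closed/maximal itemset compression and weighted ARM.
- "Bias-corrected" bootstrap is BC (not BCa); resampling is unstratified by
  default to match the emulated analysis, with a stratified option.
- The bootstrap of a separated full-data fit is refused by default;
  `on_separation="haldane_crude"` switches point estimate and replicates to
  the Haldane-corrected crude log-OR, flagged in the output.
- The additive-interaction parameterization for three exposures is the
  standard excess-odds generalization given above; alternative three-way
  decompositions exist, and the formula used is the documented contract.
- Mode imputation is the default for determinism; the iterative forest
  matches it or better on masked-truth accuracy in the tests.
- MDS uses all variants by default; positions/genes are annotation only and
  never enter computation.
- Tie-breaks everywhere are deterministic; repeated runs with one seed are
  byte-identical, and the pipeline writes a MANIFEST plus run report with
  every threshold actually applied.

## Problem sizes in the default runs

The shipped analyses and tests run at the emulated study scale (386
subjects, 196 variants) with 5000-replicate bootstraps for the headline
association run, 300–500 replicates inside Monte-Carlo calibration loops,
and 100–150 seed replications for coverage/recovery estimates — sizes
chosen so the complete analysis reproduces in minutes on one CPU.
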