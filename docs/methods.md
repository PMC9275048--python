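# Methods

This note documents the statistical model behind each pipeline stage, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Input model and gene identity

The pipeline operates on an already-normalized, log-scale gene × sample
expression matrix; upstream read processing and normalization are out of
scope. log2(TPM+1) or variance-stabilized values are the recommended
inputs. Gene identity is the uppercase symbol string throughout; no alias
resolution is attempted — a symbol present in the network but absent from
the matrix is dropped and reported, never guessed. Duplicate gene rows in
an input matrix collapse to the row with the highest mean (deterministic
and logged).

Curated interactions are read from SIF-like 3-column tables and stored as
an undirected simple graph with per-edge provenance sets. Directed source
relations (e.g. TF → target) are stored undirected because the edge
statistic treats the pair symmetrically up to a fixed orientation
convention. Merging several repositories takes the union of nodes and
edges with provenance sets merged; the merge is idempotent.

## Subgroup weighting and percolation thresholding

Each subgroup receives its own copy of the curated network, with node
weights equal to the gene's mean log-expression over the subgroup's
samples. Filtering removes nodes *strictly below* a percentile threshold
of the subgroup's weight distribution, so ties at the threshold survive.
The percentile is computed with the linear-interpolation convention
(`numpy.percentile`, method="linear"); this is fixed and documented
because different percentile conventions change the retained node set.

The default threshold is the 75th percentile. Because threshold choice is
genuinely open, `percolation_scan` reports the full connectivity profile
along a percentile grid: nodes retained, giant-connected-component (GCC)
fraction, and the size of the second-largest component. Two data-driven
summaries are provided: the largest grid percentile whose GCC still holds
at least half the retained nodes (`selected_percentile`, fraction
configurable), and the argmax of the second-largest component — the
classical percolation-transition diagnostic, since the second component
peaks where the network fragments. Isolated nodes are removed after
filtering.

Subgroup-specific networks then keep each edge only if it survived
filtering in exactly one subgroup; edges present in two or more filtered
networks are discarded from all. Consequences worth knowing: specific
edge sets are pairwise disjoint by construction, and with no filtering
(percentile 0) every edge overlaps every subgroup and all specific
networks are empty — subgroup specificity exists only where the weight
filter separates the subgroups.

## The differential-interaction statistic

For an edge (a, b) in canonical (lexicographic) order, the later gene is
regressed on the earlier one:

    y ~ intercept + x + group + group:x + covariates

with treatment coding against the largest group, one-hot categorical
covariates against their most frequent level, and numeric covariates
entered additively. A subgroup-dependent slope — the `group:x` term — is
the differential gene–gene interaction.

Fitting is Huber M-estimation, authored in this package: IRLS with
tuning constant c = 1.345 (95% Gaussian efficiency), residual scale
re-estimated each iteration as 1.4826 × MAD about the residual median,
convergence when the largest relative coefficient change drops below
1e-8, at most 50 sweeps. When the residual scale collapses (exact linear
data) it is floored at a machine-epsilon multiple and flagged. Standard
errors use the classical M-estimator asymptotic covariance
κ·s²·(X'X)⁻¹ with κ = [Σψ²/(n−p)]/[mean ψ′]², multiplied by the
Huber/Street–Carroll–Ruppert small-sample factor
K² = (1 + (p/n)·var ψ′/mean² ψ′)². statsmodels' RLM implements the same
estimator and serves as an independent cross-check in the test suite,
never as the implementation.

Significance is a joint Wald chi-square W on all `group:x` coefficients,
df = #groups − 1 (for two groups, the squared t of the single interaction
coefficient). The p-value referees W/df against F(df, 0.37·(n−k)) rather
than the asymptotic chi-square. The shrunken denominator df is a
Satterthwaite match to the sampling noise of the MAD scale: at the
Gaussian, var(log s²_MAD) ≈ 5.4/n versus 2/m for a χ²_m-based scale, so
the equivalent denominator df is ≈ 0.37·n. Measured on 20,000 null
simulations at the default cohort size (83 samples in groups 49/18/16),
the asymptotic chi-square reference is anti-conservative in the far tail
(about 2× the nominal rate at p = 0.001), which destroys BH false-
discovery control in network scans; the matched-F reference restores
validity at a small cost in power. Per-group slopes are reported as
coefficient sums (reference slope plus interaction).

Orientation is a convention, not a claim about causality; a symmetrized
analysis can be run by scanning both orientations and Bonferroni-doubling,
but the default reports the canonical orientation only. Edges with a
zero-variance gene within any group, groups smaller than 3, or unmeasured
genes are skipped with a logged reason, and BH adjustment runs over the
edges actually tested within each scanned network. Raw p-values are
always reported next to adjusted ones.

## Response models

Responder analyses binarize the three-level response (Good = 1, None = 0)
and drop Moderate responders and unlabeled samples; each class must keep
at least 3 samples. For a gene pair the logistic model

    outcome ~ intercept + g1 + g2 + ratio term + covariates

is fitted by Newton maximum likelihood (statsmodels, tol 1e-8, ≤ 100
iterations; BFGS fallback when separation makes the Hessian singular).
On log-scale inputs a literal log-ratio (g1 − g2) is exactly collinear
with the two additive terms, so the default ratio term is the centered
product (g1 − mean)(g2 − mean) — the only non-degenerate reading of a
pairwise "ratio/interaction" covariate on the log scale. A raw-scale
ratio 2^g1/2^g2 is available as an option. The design is standardized
internally (numerical stability and separation detection — |coef| > 50 on
standardized inputs, or a perfect in-sample fit, flags separation, sets
the interaction p to missing, and still reports AUCs); reported
coefficients are back-transformed to the raw scale.

Predictive value is the in-sample ROC AUC of the fitted linear predictor
with and without the ratio term. In-sample AUC is the primary metric by
design; note that removing a term can only lower the in-sample
log-likelihood, but in-sample AUC is *not* monotone in model nesting, so
`auc_without ≤ auc_with` is not asserted anywhere. AUC uses the rank
(Mann–Whitney) formula with ties counted 1/2 and equals the trapezoidal
integral of the threshold-sweep curve to numerical precision.
Dichotomizing one gene at ±1 SD is a plotting device only and never
enters fitting.

## Clusters and enrichment

Clusters are greedy modularity-maximization communities on the specific
network, computed on a canonically ordered graph for determinism;
communities below the minimum size (default 3) pool into an `unassigned`
bucket. The algorithm choice is a package decision — cluster labels are
descriptive, and the enrichment statistic, not the cluster boundary, is
the quantitative output.

Enrichment of a cluster in a gene set reports the coverage percentage
100·|cluster ∩ term|/|cluster|, rounded half-up to one decimal, and the
upper-tail hypergeometric probability of at least the observed overlap
when drawing the cluster from the universe; BH adjustment runs across
terms within a cluster. The default universe is the analyzed specific
network's gene set (configurable to all measured genes); each term is
intersected with the universe before testing.

## The synthetic-study generator

`simulate_study` emulates the statistical structure of a stratified bulk
RNA-Seq cohort: three subgroups of unequal size (default 49/18/16,
mirroring a lympho-myeloid / diffuse-myeloid / pauci-immune-fibroid
split), gene-specific baselines μ_g ~ Uniform(2, 10) with unit
between-sample variation on the log scale, planted edges whose response
gene follows y = μ_y + b_k(x − μ_x) + N(0, noise_sd) with
subgroup-specific slopes b_k (defaults 1/0/0, noise_sd 1), an age-like
covariate (mean 52.1, sd 15.9 years), and a binary response drawn from
logistic(β·t + γ·age_std) where t is the standardized centered product of
a dedicated planted pair (β default 2, γ default 0.5). The emitted
curated network contains the planted edges plus an Erdős–Rényi background
over independent genes; planted relations are oriented to match the edge
scan's canonical orientation so ground truth and statistic are directly
comparable. One seeded generator drives everything; outputs are bitwise
reproducible. By default no Moderate responders are generated (a fraction
is configurable).

The generator deliberately does not emulate count-level RNA-Seq noise
(negative binomial counts, library-size effects), batch structure,
correlated co-expression modules beyond the planted edges, or missing
data. Passing tests on synthetic studies therefore demonstrates that the
statistics behave as designed under the assumed model — Gaussian log-scale
noise, independent background genes — not that the pipeline is robust to
every artifact of real sequencing data.

## Measured operating characteristics

The validation experiments (`deggnet.validation`, also run by
`scripts/acceptance.py`) measure, under the generator's default
conditions: type-I error of the interaction test ≈ 0.04–0.06 at nominal
0.05 (500 null replicates, n = 200/group); mean false-discovery
proportion ≈ 0.02–0.04 for a BH-thresholded scan of 1 planted + 99 null
edges (q = 0.05); planted-edge detection power ≈ 0.86–0.88 at slope
difference 1, noise 1, groups (49, 18), with the slope-difference
estimate inside 2 SE of truth in ≈ 95% of replicates; the planted
predictive pair ranks first among 30 null pairs by in-sample AUC in
≈ 99–100% of replicates, with a mean ratio-term AUC gain ≈ 0.20.

On power: an ordinary least-squares oracle reaches ≈ 0.91 under the same
conditions, so a 95%-efficient robust fit with valid small-sample
inference tops out near 0.88–0.90. Choosing the anti-conservative
asymptotic reference would nudge measured power above 0.9 but breaks
false-discovery control; this package prioritizes valid p-values, since
the edge scan's purpose is BH-controlled discovery.

## Problem sizes and determinism

Validation experiments use replicate counts of 100–500 with studies of
67–200 genes and 67–83 samples — sizes chosen so the full suite runs in a
few minutes on a single CPU while keeping Monte-Carlo error well below
the decision margins (binomial SE ≤ 0.01 at 500 replicates). All
randomness flows from explicit seeds; per-replicate seeds are derived
deterministically from a base seed. Pipeline runs themselves contain no
randomness: rerunning a workflow with the same inputs produces
byte-identical tables.

## Known limitations

* The overlap-removal definition of subgroup specificity is all-or-none:
  an edge shared by two of three subgroups is discarded entirely, and no
  specificity exists without weight filtering.
* In-sample AUC overstates out-of-sample performance; the optional
  stratified cross-validation should be preferred when sample size allows.
* The robust-regression p-values rest on a moment-matched F reference,
  not an exact finite-sample distribution; extremely small groups
  (< ~10 samples) remain outside its validated range.
* Heteroscedasticity across subgroups (different residual scales per
  group) is not modeled; a strongly group-dependent noise level can
  masquerade as (or mask) a slope difference.
* Gene identity is symbol-string matching; upstream identifier curation
  is the user's responsibility.
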