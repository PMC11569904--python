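# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic data can and cannot show.

## The evaluation hierarchy

The framework is a three-level tree: domains partition the decision
problem, each domain holds criteria, and a criterion may hold subcriteria.
The packaged default (`mcda_hta/data/default_criteria.yaml`) has 5 domains
— Need for intervention; Outcomes of the intervention; Knowledge of the
intervention; Economic impact; Feasibility — with 15 criteria and 15
subcriteria. The full published table of criteria is not publicly
available cell by cell, so nodes whose exact labels could not be sourced
are marked `placeholder: true` and carry EVIDEM-style labels; the file is
data, not code, and users substitute their own validated criteria set. The
tree's *leaves* — all subcriteria plus all subcriterion-less criteria (22
in the default) — are the units that receive technology scores.

Node identifiers are positional (`d1`, `d1.c2`, `d1.c2.s1`); document
order in the configuration file is preserved and serves as the canonical
tie-breaking order everywhere downstream (rounding ties, table ordering).
Structural validation reports *every* violation, not just the first, under
stable rule ids (`unique-id`, `leaf-level`, `level-nesting`,
`parent-link`, `root-parent`, `nonempty`).

## Weight elicitation and validation

Weights come from 100-point allocations: each respondent distributes 100
points among the domains, 100 among the criteria within each domain, and
100 among the subcriteria within each criterion. The long-form CSV
(`respondent_id,sample_id,group_id,node_id,points`) is validated row-group
by row-group; a record is accepted only if it covers exactly the sibling
group's children, has no negative points, and sums to 100 exactly (the
survey interface enforced the budget, so a violation in file data is an
entry error, not noise). An opt-in `repair="proportional"` mode instead
rescales non-negative near-miss records to 100 and re-rounds them by the
largest-remainder method, flagging them as `repaired`. Respondents may
answer some sibling groups and not others; summary statistics count n per
group. Sample summaries report n, mean, SD (n−1 denominator), and median
per node; within a fully answered sibling group the means sum to 100 by
linearity.

## Weight synthesis

The two stakeholder samples differ by an order of magnitude in size (35
professionals vs 494 general-population respondents), so pooling raw
respondents would reduce the experts to noise. The final weight of each
node is instead the convex combination

  pooled = λ·mean_A + (1−λ)·mean_B,  λ = 0.5 by default,

i.e. an equal-weighted average of the two sample means. Sibling sums of
100 are preserved by linearity for any λ.

Rounding to integer percents cannot be done independently per item without
occasionally breaking the 100 budget, so each sibling group is rounded by
the largest-remainder method: floor everything, then hand the remaining
units to the largest fractional parts, ties broken by document order. This
minimizes the total absolute deviation from the unrounded percents among
all non-negative integer vectors with the correct sum. A `naive` policy
(plain nearest integer, half away from zero) is available for comparison;
groups whose naive sums break the budget are flagged in
`WeightTable.broken_sum_groups`. Normalized fractions default to
ŵ = rounded/100 (the published-table convention); normalizing the
unrounded pooled percents instead is an option, and it is what the
probabilistic sensitivity analysis uses internally.

Per-node sample differences are tested two-sided with Welch's
unequal-variance t-test (chosen over the pooled-variance form because the
two samples have visibly unequal dispersion and very unequal n) and the
Mann–Whitney–Wilcoxon rank-sum test using the normal approximation with
tie correction and no continuity correction. Both go through scipy.stats;
the test suite cross-checks them against hand-coded textbook formulas to
1e−8. The zero-variance corner (both samples constant) is reported as
p = 1 with a degeneracy flag when the constants agree and p = 0 when they
do not. Raw p-values are reported; a Holm step-down adjustment is
available but off by default.

Published integer weight tables can be imported directly
(`weight_table_from_integers`) for users without microdata; groups whose
printed percents do not sum to 100 — independent per-item rounding in the
source — are rescaled and recorded.

## The value function

Scores are elicited at leaves only. A technology's composite value is

  V = Σ_i ŵ_i Σ_j ŵ_ij Σ_k ŵ_ijk s_ijk,

the k-sum collapsing for subcriterion-less criteria (implicit subcriterion
weight of one). Treating internal-node "scores" as the weighted sums of
their descendants is the standard additive reading of the nested formula;
scoring internal nodes independently would double-count. Since each sibling
group's ŵ sum to one, effective leaf weights (path products) sum to one
and V is a convex combination of leaf scores: it inherits the score scale,
is monotone in every leaf score with positive weight, and is affinely
equivariant under score rescaling. The scale is declared per score sheet
(default [0, 1]) and never transformed implicitly. Rankings use
competition ranking (ties share a rank and are flagged); ranking across
different score scales is refused.

## Sensitivity analysis

**One-way.** A domain's or criterion's percent weight is swept over a grid
while its siblings are rescaled proportionally, preserving the 100 budget.
V is linear in the varied percent, so the curves are exactly linear and the
weight at which the top-ranked technology changes is located by linear
interpolation between adjacent grid points, not just bracketed. At the
baseline percent the unperturbed weight table is used verbatim, so the
curve passes through the baseline V bit-exactly.

**Probabilistic.** The primary method is a stratified respondent
bootstrap: each draw resamples respondents with replacement within each
sample, recomputes per-group means, pools them with the same λ, and
recomputes V and ranks for every technology. Integer rounding is skipped
inside draws — it is a presentation step, and its ±0.5-point noise would
swamp the sampling variation of small groups. Outputs are the
rank-acceptability table (fraction of draws each technology attains each
rank), mean V, and 2.5/97.5 percentile intervals, all deterministic given
the seed. Rows of the rank table always sum to one; columns sum to one
except in draws with exact value ties, which have probability zero for
continuous allocations and are counted in `n_ties` when they do occur.

For users without microdata, a Dirichlet alternative draws each group's
mean weight vector from a Dirichlet whose concentration is moment-matched
to the sampling distribution of the mean: with group means m and standard
errors se, c = avg_i[m_i(1−m_i)/se_i²] − 1 and α = c·m. This matches the
bootstrap's first two moments per node but ignores respondent-level
correlation across sibling groups; its interval widths track the
bootstrap's on the cases tested but it is an approximation, not a
replacement.

## Synthetic surveys

The generator draws each respondent × sibling-group allocation from a
Dirichlet distribution with mean equal to the profile's target vector
(after optional shrinkage toward uniform — the "equalizing bias" seen in
point-allocation exercises) and concentration controlling dispersion.
Draws are scaled to 100 points and converted to integers by
largest-remainder rounding; with probability `round_number_bias` the
rounding is done in units of 5 points instead, reproducing the
round-number clustering typical of such surveys while keeping the budget
exact by construction (no off-grid values are ever produced). Children
with target 0 receive exactly 0 points. Every emitted record passes
allocation validation, and generation is deterministic given the seed.

The default profiles mirror the published survey structure: professionals
n = 35, concentration 150, round-number bias 0.35; general population
n = 494, concentration 12 (the low concentration produces the wide,
right-skewed spread reported for that sample), round-number bias 0.65.
Domain-level targets use the published mean weights, with the one
unpublished domain per sample set to the residual so each vector sums to
100 (professionals: Feasibility 15.2; population: Economic impact 13.8);
criterion- and subcriterion-level targets default to uniform because no
item-level means are published. Equalizing bias defaults to 0 because the
published means already embody whatever equalizing the respondents did.
The concentrations and bias probabilities are calibration defaults chosen
to reproduce the described dispersion patterns qualitatively; they are not
measured quantities.

What passing tests on this synthetic data shows: the pipeline's
algorithmic correctness (budget exactness, estimator unbiasedness,
rounding optimality, test agreement, sensitivity invariants) under
realistic compositional structure. What it does not show: anything about
real respondents — item-level preference structure, correlations between a
respondent's answers across groups, demographic effects, and nonresponse
are all absent from the generator.

## Numerical choices and problem sizes

- Budget tolerance: record sums are compared to 100 at 1e−9; group mean
  sums at 1e−9; normalized-fraction sums at 1e−12.
- Largest-remainder rounding rounds inputs to 9 decimals first so float
  fuzz cannot flip a floor; remainder ties break by document order via a
  stable sort.
- Welch degrees of freedom follow Welch–Satterthwaite; all tests are
  two-sided with 0.05 as the reporting threshold.
- Distribution reports bin points in width-5 bins over [0, 100], last bin
  closed, exposing round-number clustering; the width is configurable but
  must divide 100.
- Random numbers come from `numpy.random.default_rng`; every stochastic
  artifact records its seed, and the acceptance script derives all
  sub-seeds from its single `--seed` via `SeedSequence`.
- Default problem sizes keep the full test suite under a minute on one
  CPU: 1,000 respondents for the budget-exactness sweep, 1,000 random
  hierarchies for the value-function oracle, 500 random sibling groups for
  the rounding oracle, 100 random two-sample problems for the statistical
  cross-check, n = 500 per sample × seeds 1–5 for parameter recovery, and
  a few hundred bootstrap draws in sensitivity tests (the CLI default
  remains 2,000 draws).

## Known limitations

- The equal-weighted pooling treats the two samples as fixed strata; no
  design weights or post-stratification of the population sample are
  applied.
- Leaf-only scoring is the implemented reading of the nested formula;
  frameworks that genuinely elicit independent internal-node scores need a
  different aggregation.
- The one-way sweep rescales siblings proportionally; other redistribution
  rules (e.g., absorbing the change in a single named sibling) are not
  implemented.
- Structural uncertainty over the tree itself (adding/removing criteria)
  is out of scope; sensitivity analysis covers weight uncertainty only.
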