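# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and the limitations of `ehrcf`. Everything asserted
here is computed by the test suite or `scripts/acceptance.py`; nothing is
quoted from external data.

## The estimation problem

The package targets counterfactual comorbidity effects on a binary
clinical outcome (framed as ADRD onset in adults 65+). For a binary
exposure T (the subject ever has the comorbidity during observation) and
outcome Y, the estimands are risk differences under the Neyman–Rubin
potential-outcome model:

- ATE = E[Y(1) − Y(0)] over the analysis cohort,
- ATT = E[Y(1) − Y(0) | T = 1] (effect among the exposed),
- ATC = E[Y(1) − Y(0) | T = 0] (effect among the unexposed).

Identification rests on conditional exchangeability given the adjustment
set read off a learned causal graph (parents of T plus parents of Y),
positivity (enforced numerically by propensity clipping), and
no-interference. None of these are testable on real data; the synthetic
generator exists precisely so the pipeline can be validated where they
hold by construction.

## Synthetic cohort generator

Each node (phenotype or outcome) is Bernoulli with a logistic structural
equation over its parents' presences plus a per-group intercept shift;
occurrence counts given presence are shifted Poisson, `1 + Pois(rate − 1)`,
so a present condition has at least one billing record and the count
distribution is right-skewed like real utilisation data. The tier ordering
(1 = established chronic risk factors, 2 = candidate comorbidities,
3 = outcome) is enforced at validation: no edge may enter tier 1 from
above, and the outcome has no outgoing edges.

Key defaults, chosen once as epidemiologically plausible values:

| quantity | default | reasoning |
|---|---|---|
| edge weights | 0.7–1.25 log-odds | odds ratios ≈ 2–3.5, strong but realistic comorbidity associations |
| tier-1 intercepts | −2.0 … −0.4 | prevalences ≈ 12–55% in a 65+ cohort |
| group shifts | +0.4 … +0.7 on hypertension, diabetes, obesity | documented higher baseline prevalence in the reference group; creates measurable cross-group confounding |
| count rates | 1.5–4 | a handful of billing events per active condition |
| ages | start U(65, 85), duration 0.5 + Exp(2.5 y) | eligibility floor at 65, median follow-up of a couple of years |
| censoring | 20% of non-outcome subjects truncated uniformly | emulates administrative dropout qualitatively only |

Randomness is counter-based per subject (one row-major uniform draw), so
enlarging `n_subjects` appends subjects without reshuffling existing ones,
and every subject-level variable is an inverse transform of that row.

The **do-operator oracle** simulates each replicate twice from shared
uniforms with the treatment clamped to 1 and to 0. Because presence is a
deterministic function of the uniforms, non-descendants of the treatment
are bit-identical across arms and the paired difference estimates the
interventional contrast with small Monte-Carlo error (reported as
`mc_se`). The oracle is itself validated against exact enumeration over
all binary parent configurations in the test suite.

The packaged `confounded_spec` sets the direct T→Y weight to 1.25, solved
by exact enumeration so the true ATE is 0.25 — a calibrated reference
point for effect-recovery experiments.

What the generator does **not** emulate: visit-level timing, code-level
ICD granularity, diagnostic error/missingness correlated with utilisation,
and unobserved confounding. Passing tests therefore demonstrate
correctness of the machinery under the stated assumptions, not robustness
to their violation on real EHR data.

## Features

Diagnosis events are grouped many-to-one through a user-supplied code map
(the real PheWAS hierarchy is licensed and is not shipped; any two-column
TSV works). The prevalence filter keeps phenotypes recorded in strictly
more than `min_prevalence` (default 5%) of subjects, capped at the top
`top_k` (default 100) by prevalence; the filter population is the
post-case/control-matching analysis cohort by default. Counts transform as
`log2(1 + count)`; the transform is strictly monotone and exactly
invertible on integers, and a provenance flag prevents double transforms
and prevents treatment binarisation from running on transformed values.
One event row = one occurrence; no per-day deduplication is applied (a
switch exists, default off).

## Matching

**Case/control (stage 1).** Exact on sex, greedy nearest-neighbour on
Euclidean distance over (age_start, age_end), without replacement,
deterministic order (cases by subject id; ties by lowest control id).
Each matched control's window is truncated to its case's end age so both
members of a pair have equal opportunity to accrue diagnoses; controls
whose truncated window would fall under the 0.5-year minimum are rejected
with one repair pass of re-matching. Windows are never lengthened.

**Cross-group (stage 2).** Logistic propensity of group membership on
age, sex, and the tier-1 known-risk comorbidity presence indicators,
scores clipped to [1e−6, 1−1e−6]. Greedy 1:1 nearest-neighbour on the
logit scale, without replacement, caliper = 0.2 × SD of the logit scores
(standard practice; the radius option pre-restricts candidates
absolutely). Subjects are processed hardest-first (descending |logit|),
which makes the greedy pairing deterministic and row-order invariant. By
default matching is stratified by outcome status so the case/control
composition is preserved across groups. Greedy rather than optimal
matching is deliberate: it is the reproducible baseline, and balance —
not pairing optimality — is the quantity that matters downstream.

**Balance.** Standardized bias = |mean difference| / SD in the designated
reference group (computed pre-matching, so before/after are on one
scale), with the conventional 0.10 cutoff. Count covariates are compared
as presence indicators. A zero reference SD with differing means is
reported as undefined (NaN) rather than silently passed.

## Structure learning

The "stable" PC variant freezes the adjacency structure at the start of
each conditioning-set size, which removes order dependence and keeps the
voting ensemble reproducible. The default conditional-independence test
is Fisher-z on partial correlations,
`z = arctanh(r) · sqrt(n − |S| − 3)`; the binary outcome column is tested
with the same statistic (pragmatic and common for mixed data; a G² test
for all-binary data and a logistic likelihood-ratio test are selectable).
Zero-variance columns are declared independent with a logged warning.
`max_cond_size` caps the conditioning-set size (default 3 in the
pipeline) — with ~100 log-count features the exhaustive search is
otherwise exponential; at the packaged model's dimensions the cap is not
binding.

Orientation: tier-crossing edges are directed low→high tier first
(background knowledge), v-structures are oriented where the collider is
outside the recorded separating set, then Meek rules propagate to
closure. Rule 2 is implemented as a generalized acyclicity rule (orient
a→b whenever b→a would close any directed cycle), which subsumes the
textbook two-edge version; rules 1, 3 and 4 are literal. Conflicting
demands leave an edge unoriented and are logged, never overwritten. The
whole skeleton+orientation path, run with an exact d-separation oracle,
reproduces the brute-force CPDAG (union of orientations over the
enumerated Markov equivalence class) on randomized small-DAG suites —
this is an acceptance property.

**Ensemble.** Subjects are partitioned into K = 10 folds; run k drops
fold k (a 90% subsample). Only *directed* edges vote: an edge left
unoriented within a tier carries no directional evidence. Consensus
requires strictly more than `vote_threshold · K` votes (majority);
outcome parents are reported at ≥ 9 of 10 ("more than nine" is read as
≥ 9 — on a 0–10 vote scale a strictly-greater reading would leave 10 as
the only admissible count, inconsistent with reporting edges at seven
votes). Every per-fold and consensus graph is asserted tier-clean.

**Graph distances.** SHD counts unordered node pairs whose edge status
(absent / → / ← / both) differs; a misoriented edge costs 1. GED uses
unit costs for node insert/delete/label-substitute and for any edit of a
pair's edge status — including orientation flips. Under this accounting
the identity correspondence realises the SHD, so GED ≤ SHD on identical
labelled node sets; defining reversal as delete+insert (cost 2) would
break that ordering, which is why the substitution convention was chosen.
Exact GED is branch-and-bound over node correspondences up to
`exact_node_limit` (default 10) nodes; beyond that a greedy
label-matching upper bound is returned with a warning.

## Effect estimation

The propensity e(X) is an unpenalized logistic MLE with scores clipped to
[0.01, 0.99] (overlap enforcement). Separation — detected as perfect
in-sample classification, where the MLE diverges — triggers a penalized
(L2, C = 1) refit with a warning, never unbounded scores. An overfit
guard rejects more covariates than 10% of n.

Adjustment covariates enter as `log2(1+count)` **plus** a presence
indicator per comorbidity (`hurdle_design`). A single linear log-count
term cannot represent the dominant has-the-condition step of a
zero-inflated count covariate, and the residual propensity
misspecification leaves a small systematic bias in weighted estimates;
the hurdle pair nests the step function and removes it.

- **IPTW (default):** Hájek self-normalized — each arm's weighted outcome
  sum divided by that arm's weight sum (ATE weights 1/e and 1/(1−e); ATT
  1 and e/(1−e); ATC symmetric). Rescaling all weights by any positive
  constant provably cannot move the estimate, and under e ≡ 0.5 the
  estimator reduces exactly to the difference of arm means (both asserted
  exactly in tests). The unnormalised Horvitz–Thompson sums (divide by n
  or n₁) are available via `normalize=False`; the two differ on finite
  samples, and the self-normalized form is the default because it is the
  variance-stable estimator of choice.
- **PS matching:** 1-nearest-neighbour on the logit score, with
  replacement, averaging within-pair differences over the estimand's
  reference arm. Known to be the most sensitive of the three to
  propensity-model coarseness (near-discrete score support makes
  cross-stratum matches possible); it is reported alongside, not used as
  the headline estimator.
- **PS stratification:** score-quintile strata (n_strata = 5), stratum
  differences pooled by stratum size (ATE), exposed count (ATT) or
  unexposed count (ATC); strata missing an arm are dropped and counted.

**Bootstrap.** Percentile intervals from B = 100 subject-level resamples;
each replicate refits the propensity model and re-runs the estimator.
The learned graph is *not* re-learned per replicate — the interval
quantifies estimation uncertainty given the structure, not structural
uncertainty. Replicate failures are dropped and counted; more than 20%
aborts.

## Permutation refutation

Fisher's sharp null (no effect for any subject) is tested by shuffling T
(a permutation, so the exposure margin is preserved exactly) and
re-running the full estimator B = 100 times. Two numbers are reported
deliberately: the standard add-one two-sided Monte-Carlo p-value, where
*small* values support a real effect, and the mean permuted estimate,
whose closeness to zero is the placebo-style sanity check used by common
refutation tooling — the two readings are easy to conflate, so both are
given explicitly. The add-one construction keeps p ≥ 1/(B+1) > 0.

## Pipeline determinism and problem sizes

Every stage draws from a labelled sub-stream of the master seed (CRC-32
of the stage label mixed into a SeedSequence), so group A and B analyses
are independent yet reproducible, and a rerun with the same config is
bit-identical at the JSON-report level.

The packaged study sizes — 10,000 subjects for structure recovery and
balance, 20,000 for effect recovery, 400 per replicate for permutation
calibration, 100-replicate seed sweeps — were chosen so the full
validation battery represents each statistical claim at a scale where its
expected behaviour is unambiguous while the whole suite stays a
desk-scale computation.

## Known limitations

- Fisher-z on a binary outcome column is an approximation; the G²/logistic
  tests cover only parts of the mixed-data space.
- Greedy matching is not optimal matching; with heavy cross-group
  imbalance it can leave reference subjects unmatched (they are reported,
  never dropped silently).
- GED beyond `exact_node_limit` is an upper bound.
- The bootstrap conditions on the learned graph; structural uncertainty
  is expressed only through the vote counts.
- No latent-variable discovery (FCI), no score-based learners, no
  doubly-robust or TMLE estimators, no time-varying exposure — all out of
  scope by design.
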