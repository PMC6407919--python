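# Methods

This note records the modelling assumptions, parameter choices, and
numerical decisions behind the package, and what the synthetic-data
tests do and do not establish.

## Interaction screening

P(target | configuration, arm) is estimated from cell counts with
additive (Laplace) smoothing, default pseudo-count 1.  Unsmoothed
estimates hit 0/1 in sparse cells and force Hellinger distances of
exactly 1, which would let noise dominate the maxima; smoothing can be
disabled (`smoothing=0`) when a table encodes exact probabilities, as in
the worked examples.  Configurations with fewer than `min_support`
records (default 10) in either treatment arm are excluded from both
maxima with a logged warning — a cell that thin supports no contrast.

Two readings of "not effective" are implemented.  The default counts
deleterious *and* neutral configurations in the non-effective maximum
(the generalized multi-valued rule); `require_deleterious=True` demands
a strictly harmful configuration, the stricter binary-feature reading.
Probabilities equal within 1e-12 are classified neutral.

Ranking is deterministic: strength descending, then smaller set size,
then lexicographic feature names.  A configurable cap (default 20 000
candidate sets per treatment) guards the combinatorial enumeration.

### Confounder check

Full equivalence-class search is out of scope; the check uses greedy
single-edge hill climbing (add/delete/reverse) on the BDeu score
(α = 1 by default; the score is computed in log-gamma arithmetic because
the raw gamma-ratio product underflows within ~50 records), with the
candidate set's edges into the target forced and immutable.  Greedy
search cannot orient score-equivalent edges — Z→R and R→Z tie exactly
when Z has no other neighbours — so the candidate common causes are the
variables *adjacent to or ancestors of* both treatment and target in the
learned graph, a deliberate over-approximation.  The decisive filter is
the G² likelihood-ratio test of independence from the target given the
candidate set, at α = 0.05, with degrees of freedom reduced for empty
rows/columns per stratum.

## Bayesian-network core

Exact inference is variable elimination with a min-degree ordering;
the test suite cross-checks it against full joint enumeration.  Parent
configurations are indexed row-major over the parents in declaration
order, first parent slowest; every module that exchanges flattened
per-configuration vectors uses this one convention.  Evidence with
probability 0 raises an error rather than returning a zero distribution:
a query conditioned on an impossible event has no answer, and silently
returning zeros would propagate NaNs downstream.

## Outcome model

The leaky noisy-OR with interacting causes places one hidden binary
variable per cause group.  The closed form
P(T=0 | causes) = q_Leak · ∏ q_g[j_g] is used everywhere; the tests
verify it against enumeration over hidden assignments.

**Identifiability and baseline anchoring.**  With every configuration's
q free, the likelihood is invariant under q_g[·] → c·q_g[·],
q_Leak → q_Leak / ∏ c_g: only products are identified, so
per-configuration estimates are meaningless without a normalization.
`em_fit` therefore anchors each group's baseline configuration (all
parents at their first state) at q = 1 by default — the classic noisy-OR
convention that a cause at baseline cannot trigger the effect — which
makes the remaining parameters identifiable and lets recovery tests
compare against planted truth.  `anchor_baseline=False` restores the
fully free parameterization.  State order is consequently meaningful:
the first state of every variable is its baseline (e.g. `no` before
`yes`).

**EM details.**  Initialization: q = 0.5 everywhere (or uniform draws
under `random_init` with a seed), leak = 1 − empirical adverse rate.
Convergence: relative log-likelihood change below `tol` (default 1e-6),
`max_iter` 500.  Estimates are clipped to [1e-6, 1 − 1e-6] to avoid
absorbing states at the boundary.  Records with a missing cause or
target value are excluded; imputation is an upstream, separate step.
Only the hidden-layer parameters are estimated — the model is
conditional on the causes, so no distribution over causes is learned.

The ordinal extension stores a full distribution over levels per
configuration (and a free leak distribution); cumulative probabilities
multiply across groups because the target is the maximum hidden level.
Its parameters are not fitted by EM here — the extension exists for
prediction and generation.

## Decision layer

Expected-utility maximization enumerates all 2^T joint assignments
(T ≤ 6 in the intended use, 64 assignments); no heuristic solver is
needed or used.  Because each hidden group contains at most one
treatment, per-treatment optimization decomposes — the tests assert the
equivalence rather than assuming it.  Ties break toward "no treatment":
intervention carries real costs that a 0/1 outcome utility does not see,
so indifference should not trigger treatment.  Recommendation requires a
complete feature assignment; marginalizing over unobserved features is
out of scope.

## Evaluation harness

Folds are a seeded random partition with sizes differing by at most one.
Both Wald and Wilson intervals are provided (via statsmodels) because
published tables of this kind mix the two; Wilson is the default, Wald
is clipped to [0, 1] at the boundary.  Proportions are kept at full
precision and rounded only for display.  A treatment arm with zero
deviating (or zero following) records reports its proportion as
unavailable rather than 0/0.

## Synthetic-data generator

The generator emulates a registry table: features drawn iid from stated
marginals (uniform by default — no joint feature distribution is
claimed), treatments assigned by a per-treatment policy table
P(taken | policy parents) that stands in for physician behaviour, hidden
groups activated with probability 1 − q at the realized configuration,
target = OR (or max level), and completely-at-random missingness.

The 23-variable registry preset plants a HER2-inhibitor × HER2 ×
node-status interaction, a chemo × node-status interaction, and a grade
main effect, with leak 0.98 chosen once so the enumerated marginal
adverse rate is ≈ 0.082, matching the realistic prior of roughly 8% for
5-year distant metastasis in a mixed breast-cancer cohort.  The
beneficial-subgroup preset (10 000 records by default) gives one therapy
a strong benefit for biomarker-positive patients and mild harm
otherwise, with a coin-flip policy so about half the cohort deviates
from optimal; the confounded preset routes the policy through a
disease-burden variable that also drives the outcome.

What passing tests show — and what they do not: the generator's
independence of features, exact policy form, and noiseless adherence to
the noisy-OR mechanism are idealizations.  Recovery and evaluation
results on these data demonstrate correctness of the algorithms under
their own assumptions, not performance on real registries, where
correlated features, informative missingness, unmeasured confounding and
model misfit all bite.

## Problem sizes

Test and script scales were chosen to exercise the statistics at
meaningful power: parameter recovery at n = 20 000 (every planted
configuration with ≥ 100 supporting records recovered within ±0.03),
ranking of the planted set at n = 50 000, cross-validation at n = 10 000
with 5 folds, confounder screening at n = 4 000.

## File formats

Tabular I/O is CSV (RFC-4180, UTF-8, header row) with a configurable
missing marker, default `NULL`.  Networks and outcome models serialize
to plain structured text (YAML): a Bayesian-network file lists
`variables` (name + ordered states), `edges`, and `cpts` — one flattened
row per parent configuration in the package's index order; an outcome
model file (`kind: camil`) lists `causes`, `groups` (parents + flattened
`q` vector), `leak_q`, `target`, and `adverse_state`.  Round-trips are
bit-exact for the parameter vectors.  Reports (rankings,
recommendations, evaluation tables) are TSV.

## Known limitations

* Treatments must be binary; the target binary or ordinal.  No
  continuous variables, censoring, or time-to-event outcomes.
* Structure learning is limited to the forced-edge hill-climbing used by
  the confounder check; the two-layer outcome structure itself comes
  from interaction screening, not search.
* Nearest-neighbour imputation uses pairwise-complete Hamming distance
  with k = 5, record-order tie-breaks, and votes from original values
  only; it is deterministic but crude, and informative missingness will
  bias it.
* The confounder check can only flag measured variables; a latent common
  cause (e.g. unrecorded clinical judgement) is invisible to it.
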