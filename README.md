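# dpac

Decision support for categorical clinical data: learn how treatments
interact with patient features to affect a binary outcome, assemble the
interactions into a leaky noisy-OR outcome model, and recommend the
per-patient treatment combination that maximizes expected utility.

The package is aimed at biostatisticians working with registry-style
tables — rows of categorical clinical features, binary treatment
indicators, and an outcome such as 5-year distant metastasis — who want
patient-specific treatment recommendations with an explicit causal-model
backbone rather than a black-box classifier.

## The method

**Interaction screening (TFI).** For a binary treatment *R*, feature set
*X* (1–4 variables) and binary target *T*, estimate P(*T* | *x*, *R*) at
every configuration *x* of *X* and compare the treated and untreated arms
with the Hellinger distance
H(p, q) = (1/√2)·‖√p − √q‖₂ ∈ [0, 1].
A configuration is *effective* if treatment lowers the adverse
probability, *deleterious* if it raises it, *neutral* otherwise.  The
interaction strength is

    strength = min( max H over effective configs,
                    max H over non-effective configs )

and 0 when either class is empty: a treatment that helps everywhere (or
nowhere) needs no feature to decide.  Candidate sets are ranked by
strength; the winner is screened for hidden common causes by forcing the
edges *R* → *T* and *X* → *T*, hill-climbing a BDeu-scored Bayesian
network over all variables, and G²-testing every variable connected to
both *R* and *T* for conditional independence of *T* given *X*.

**Outcome model (leaky noisy-OR with interacting causes).** Each selected
interaction (or lone cause) feeds one hidden binary variable H_g with
per-configuration inhibition q_g[j] = P(H_g = 0 | parents in config j); a
Leak covers unmodelled causes.  The target is the OR of the hidden layer:

    P(T = 0 | causes) = q_Leak · ∏_g q_g[j_g(causes)]

Parameters are learned by EM over the hidden layer (closed-form E and M
steps; the log-likelihood trace is non-decreasing).  An ordinal-target
variant gives hidden variables ordered levels and takes their maximum.

**Decision layer.** Treatments become decision nodes; expected utility of
a joint treatment assignment is the outcome utility (default 1 for the
good state, 0 for the adverse state) minus a disutility *x* for each
treatment taken.  *x* comes from the standard gamble: a patient
indifferent at probability *p* of the good outcome without treatment has
x = 1 − p.  Recommendations enumerate all 2^T assignments; ties break
toward less intervention.

**Evaluation.** k-fold cross-validation re-learns the pipeline per fold
and tallies, per treatment, N1/K1 (followed the advice / good outcome)
and N2/K2 (deviated / good outcome), with Wald or Wilson binomial
confidence intervals on K1/N1 and K2/N2.

## Worked example

`examples/04_cross_validation.py` generates a 10 000-record synthetic
cohort in which one therapy helps only biomarker-positive patients (and
harms the rest), then cross-validates the full pipeline:

```
N1=5030  K1=4451  N2=4970  K2=3526
P(no metastasis | followed advice)  = 0.885 (95% CI 0.876-0.893)
P(no metastasis | deviated)         = 0.709 (95% CI 0.697-0.722)
non-overlapping intervals: the planted subgroup benefit is real
```

Patients whose actual treatment matched the model's advice stayed
metastasis-free at 88.5% versus 70.9% for those who deviated; the
non-overlapping intervals show the pipeline recovered the planted
subgroup rule.  The other example scripts demonstrate interaction
screening (`01`), EM parameter recovery against ground truth (`02`),
per-patient recommendations with standard-gamble costs (`03`), and the
confounder check (`05`).

A thin CLI wraps the same pipeline: `dpac simulate | impute | tfi | fit |
recommend | evaluate` (see `dpac --help`).

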