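# Methods

## Task model

A session is 4 cue conditions × `per_cue_per_block` × `n_blocks` trials
(default 4 × 10 × 3 = 120), each condition appearing exactly
`per_cue_per_block` times per block in a seeded random order, target circle
uniformly left/right. Feedback is probabilistic: a correct Go/NoGo decision
delivers the condition's better outcome (win cues: +1 vs 0; punishment
cues: 0 vs −1) with probability `p_better` = 0.8. The paradigm literature
specifies the contingency only for correct decisions; we mirror it
(incorrect decisions get the better outcome with probability
1 − `p_better`), and expose `p_better_incorrect` for asymmetric designs.

A key press on the wrong side of the target counts as a Go for learning and
accuracy — the instrumental contingency depends only on the Go/NoGo
dichotomy — while the wrong-side press rate feeds the localization-error
exclusion (rate > 0.45 of presses excludes the session). Uniform responders
(Go on every trial, or no press at all) are excluded as carrying no
instrumental signal; never-pressing subjects also have an undefined
localization rate, so the uniform-response rule subsumes that degenerate
case. Exclusion is applied per session and is idempotent.

## Learning models

All variants share delta-rule value learning toward ρ·r with learning rate
α, a two-option softmax over action weights, and optionally: an irreducible
lapse ξ mixing in uniform choice, a constant Go bias b, and a Pavlovian
term coupling the cue's state value V(s) into the Go weight — either
proportionally (π·V) or through its sign only (π·sgn(V)). Conventions the
equations leave open were fixed as follows:

* **Initial values.** Q and V start at 0 — a neutral prior over outcomes;
  with r ∈ {−1, 0, 1} this also bounds |Q|, |V| ≤ max(ρ_rew, ρ_pun).
* **ρ at r = 0.** ρ multiplies r, so neutral outcomes update values toward
  0 regardless of sensitivity; with split sensitivities ρ_rew applies to
  r = +1 and ρ_pun to r = −1.
* **sgn(0) = 0.** Before any valenced evidence about a cue the constant
  Pavlovian variant exerts no pull.
* **Constant variant bookkeeping.** V itself is maintained at full
  magnitude by the same delta rule; the sign is taken only inside the
  action weight. Consequently the scaled and constant variants share
  identical Q/V trajectories on identical data and differ only in the
  weight rule (a tested invariant).
* **V shares α with Q** (one learning rate governs both instrumental and
  Pavlovian value updates). An optional `separate_learning_rates` flag
  splits α by outcome sign (neutral outcomes keyed to the cue's valence);
  it is off in the default five-model ladder, which follows the
  split-sensitivity convention: RW, RW+noise, RW+noise+bias,
  RW(rew/pun)+noise+bias+pav, RW(rew/pun)+noise+bias+pav(const).

The session log-likelihood replays the observed trial sequence, scoring
each observed action under the current weights before updating values with
the observed action and outcome. The replay loop is JIT-compiled (numba);
a pure-Python composition of the public primitives computes the same
quantity and anchors the equivalence tests. With ξ > 0 probabilities are
bounded below by ξ/2; with ξ = 0 they are floored at 1e−12 before the log
so degenerate parameterizations stay finite.

## Hierarchical fitting

Parameters are estimated in unconstrained space (logit for (0,1)
parameters, log for (0,∞), identity for b) under an independent Gaussian
group prior per parameter. The empirical-Bayes EM loop:

* **E-step.** Per subject, L-BFGS-B maximizes log-likelihood + log-prior.
  The first EM iteration uses 5 starts (prior mean plus prior-scaled
  jitter); later iterations warm-start from the previous mode, and the
  returned objective never falls below any start point. The curvature is a
  central finite-difference Hessian (relative step 1e−3), symmetrized and
  regularized by adding ε·I (doubling ε) until Cholesky succeeds. Restart
  jitter is keyed to the session's data content, so byte-identical sessions
  get byte-identical fits.
* **M-step.** Prior mean ← mean of posterior modes; prior variance ←
  mean(mode² + diag(H⁻¹)) − mean², floored at 1e−6 to keep the prior
  proper.
* **Convergence.** Stop when no hyperparameter (mean or variance) moves by
  more than 1e−3, or after 100 iterations. Initialization is N(0, 6.25)
  for every parameter — weakly informative across each constrained range.

**iBIC.** Per subject the evidence ∫ p(data|θ) p(θ|prior) dθ is estimated
by log-mean-exp of the likelihood over 10,000 prior draws (seeded;
zero-likelihood draws are harmless in log space), and
iBIC = −2·Σᵢ log p̂ᵢ + 2k·log(N), with k the number of model parameters
(two hyperparameters each) and N the total number of choices in the cohort
(a subjects-based penalty is available via `penalty_obs`). Doubling the
Monte-Carlo sample moves cohort-level iBIC values by well under the
between-model gaps of interest (a tested stability property).

## Synthetic cohorts and what they do (not) show

`generate_cohort` draws per-subject unconstrained parameters from a
configurable Gaussian generating prior; session-2 parameters are
constructed per parameter as a bivariate Gaussian with population
correlation `between_session_correlation`, so the generator's stability is
exactly known. Default generating values are literature-typical for this
paradigm: α ≈ 0.2 (logit mean −1.386, sd 0.7), ρ ≈ 4 (log mean 1.386, sd
0.5), ξ ≈ 0.1 (logit mean −2.197, sd 0.7), b ≈ 0.4 (sd 0.5), π ≈ 0.8 (log
mean −0.223, sd 0.7). One root seed spawns child streams per
subject/session, so cohorts are bit-reproducible.

The generator emulates the computational content of the paradigm —
schedules, contingencies, valence structure, parameter stability — but not
reaction times, attention drift within a session, practice effects between
sessions, or any stimulus-level features. Passing recovery and reliability
tests therefore demonstrates that *the pipeline is correct and adequately
powered under the model's own assumptions*; it cannot certify that human
data satisfy those assumptions.

## Validation experiments and their scale

Desk-scale experiments (seeded, run inside the test suite) use cohorts of
60–100 subjects at the standard 120 trials/session: parameter recovery
(true-vs-refitted correlations, log scale for positive parameters), model
recovery over the five-variant ladder (60 subjects), and an end-to-end
two-session reliability run (100 subjects, generated stability 0.6). These
sizes match the study scale the package targets while keeping the full
suite in the minutes range.

A known limitation surfaced by the hyperparameter-recovery experiment: at
120 trials/subject, α and ξ are weakly identified per subject, and the
maximum-marginal-likelihood group means for them carry a sampling SE of
roughly 0.15 unconstrained units at 100 subjects. Individual seeded
cohorts can therefore miss the generating mean by ~0.3 on those two
parameters even though the estimator is unbiased: recomputing exact
posterior means by prior-sampling importance weighting reproduces the same
group means, repeated cohorts scatter symmetrically around the truth, and
re-initializing EM at the generating values returns to the same fixed
point. Reliability conclusions are unaffected — they depend on
between-subject ordering, which is recovered well (r ≈ 0.6–0.85 against
truth) — but point recovery of group-level α/ξ means at this trial count
should be interpreted with that noise floor in mind.

## Statistics

Repeated-measures ANOVAs are computed as 1-df within-subject orthogonal
contrasts: each effect's F on (1, n−1) is the squared paired t of its
contrast (action, valence, session and their interactions; the
action×valence contrast is the Pavlovian crossover). This reproduces
`statsmodels` AnovaRM to numerical precision and is cross-checked against
it in the tests. Variance-ratio F-tests report var(x)/var(y) on
(n−1, m−1) df with an upper-tail p by convention (two-tailed optional).
Identical paired samples return t = 0, p = 1; constant nonzero differences
are rejected as undefined. Pearson reliabilities use the t-based p on n−2
df and Fisher-z 95% intervals tanh(atanh r ± 1.96/√(n−3)); the same
interval around an assumed r gives the planning precision at a candidate
sample size. Strictly positive parameters (π, ρ) are correlated on the log
scale; α, ξ, b raw. No multiple-testing correction is applied, matching
the descriptive reporting style of this literature.
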