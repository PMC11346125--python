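# Methods

## Model and estimation

raschkit fits the dichotomous Rasch model, P(X_ni = 1) =
exp(θ_n − δ_i)/(1 + exp(θ_n − δ_i)), with person ability θ and item
difficulty δ in natural-log logits. The logistic is evaluated through
`scipy.special.expit`, which is overflow-safe out to arbitrarily large
|θ − δ|; no probit or rescaled metrics are offered.

Because raw scores are sufficient, maximum likelihood reduces to score
equations: Σ_i P_ni = r_n for persons and Σ_n P_ni = s_i for items. Both
are solved by Newton–Raphson with the information-weighted step
Δθ = (r − ΣP)/ΣPQ, damped to at most 1 logit per iteration so a start far
from the root cannot overshoot (the score function is strictly increasing,
so the damped iteration is globally convergent).

Joint calibration (JMLE) alternates a full person-step solve with one
damped item update per outer cycle, re-centres difficulties to mean 0 each
cycle (the identification constraint), and stops when the largest
parameter change in a cycle drops below the tolerance (default 1e-4
logits, at most 100 cycles; non-convergence is flagged on the result and
the best iterate returned). The alternating scheme was chosen to match
the behaviour of the classic desktop Rasch engines, which estimate both
facets jointly from the same response matrix.

Known JMLE properties handled explicitly:

* **Bias.** JMLE difficulty estimates are inconsistent at fixed test
  length, inflated by roughly L/(L−1). The standard (L−1)/L shrinkage is
  applied to the final centred difficulties (on by default). A small
  outward bias remains at the most extreme items (about 0.1 logit for a
  10-item test at N = 300), which is visible in the recovery numbers and
  is a known limitation of the estimator class rather than of the
  implementation.
* **Extreme scores.** A zero or perfect raw score has no finite ML
  estimate. Such scores are replaced by r + adj (zero) or r − adj
  (perfect) before solving; adj defaults to 0.25 score points and is
  user-configurable in (0, 1). Different adjustment conventions move a
  perfect scorer's measure by a few tenths of a logit on a 10-item test —
  with adj = 0.25 on the packaged difficulties it is 4.58 logits, with
  adj = 0.3 about 4.39 — which is why downstream comparisons of extreme
  measures should state the convention. Persons with extreme scores are
  excluded from the item step (their responses carry no item contrast)
  and scored against the final difficulties afterwards.
* **Degenerate items.** An item everyone got right (or wrong) is dropped
  from calibration with a warning and listed on the result.
* **Missing data.** Missing cells are excluded cell-wise from every score
  equation, residual and fit sum (pairwise-present likelihood).

Standard errors are the reciprocal square root of the observed test
information, SE(θ) = 1/√(Σ_i P_ni Q_ni), and dually for items.

## Rating-scale category probabilities

The rating-scale category-probability function (Andrich parameterisation:
category weight exp Σ_{j≤k}(θ − δ − τ_j), normalised by log-sum-exp) is
provided for completeness of the probability layer. With two categories
and τ = [0] it reduces to the dichotomous model exactly, and that
reduction is the only path the rest of the package uses; estimation of τ
from polytomous data is deliberately out of scope.

## Fit statistics

Standardized residuals are z_ni = (x_ni − P_ni)/√(P_ni Q_ni); for a
correct response z² = Q/P and for an incorrect one z² = P/Q, closed forms
the tests use as oracles. Per margin (item or person):

* outfit MNSQ = mean z² — unweighted, dominated by unexpected responses
  far from the margin's location;
* infit MNSQ = Σ(x − P)² / ΣPQ — information-weighted, sensitive near the
  location.

Both have expectation ≈ 1 under the model. The conventional screens —
items flagged above infit 1.5, persons flagged as aberrant above outfit
2.0 — are reported, not enforced. Persons with adjusted extreme scores are
included in residual computations at their adjusted θ̂, so a perfect
responder still gets a KIDMAP and an outfit value.

The item-level chi-square fit bins calibrated persons into equal-count
ability strata (default 5; configurable) and compares each stratum's
observed mean item score with the model expectation:
χ² = Σ_s (obs_s − exp_s)² / Var(mean_s), Var(mean_s) = Σ P Q / n_s²,
referred to the upper tail of χ² with n_strata − 1 df. Empty strata (an
artefact of the discreteness of θ̂ when raw scores take few values) are
merged into a neighbour with a warning. With a 10-item test θ̂ takes only
nine interior values, so the stratum test has modest power; it reliably
flags strongly non-Rasch items (discrimination ≈ 3) but not mild slope
departures.

## Differential item functioning

The primary DIF statistic is the anchored separate-calibration contrast:
person abilities are fixed at the joint calibration, each group's item
difficulty is re-estimated from that group's responses alone, and the
contrast δ₁ − δ₂ is tested with Wald z against √(se₁² + se₂²). This is
the approach of the classic desktop engines and needs no extra modelling
assumptions. A Mantel–Haenszel variant (ability-stratified 2×2 common
odds ratio test) is available as a clearly second-line option. No
multiple-testing correction is applied by default; Bonferroni is a flag.
The standardized mean difference reported alongside divides the contrast
by the root-mean-square of the two group standard errors — a display
scaling for the forest plot, not a test statistic. Persons with extreme
raw scores are excluded from DIF (their anchored abilities are adjustment
artefacts), and an item with zero score variance within a group is
reported not-estimable rather than guessed.

## Grades, KIDMAP, Wright map, group tests

Person measures are banded A–E at cut-points 3.0, 1.5, −1.5, −3.0 logits,
upper-exclusive (θ > 3.0 is A; θ = 3.0 is B; θ ≤ −3.0 is E). The
cut-points are a `GradeBands` value object, so other conventions are one
constructor call away.

A KIDMAP lists, for one person, every administered item's difficulty,
observed response, model expectation at θ̂ and standardized residual, with
items sorted by difficulty and classified into expected/unexpected ×
correct/incorrect quadrants at |z| = 2.

The Wright map histograms θ̂ (default bin width 0.5 logits, half-open
bins), overall and per group, against the calibrated item locations on the
shared logit axis. Group differences in measures are tested with ordinary
one-way ANOVA on θ̂ (two-level factors also report t with F = t²);
measurement error in θ̂ is ignored by design, matching common reporting
practice, and an SE-weighted comparison is out of scope.

All tabular outputs (items.tsv, persons.tsv, dif.tsv) round to 2 decimals;
kidmap.json keeps full precision. SVG plots are rendered from the tables,
which remain the tested surface.

## Simulation design

The generator draws abilities from Normal(0, 1) by default — the mean and
spread are configurable, and the default documents an assumption, not a
measured population — and fills the response matrix with independent
Bernoulli draws at the model probabilities. Group labels are iid with
probability 0.5 for the first label. One integer seed drives abilities,
responses and labels in a fixed order, so runs are bit-reproducible, and
the true abilities ride along for recovery checks.

The packaged study design is 300 simulees on 10 items at difficulties
(−2.43, −1.78, −1.48, −0.64, −0.1, 0.33, 0.59, 1.34, 1.7, 2.47) logits —
note they sum to zero, consistent with the centring convention — plus one
appended all-correct responder. What the simulator does *not* emulate:
guessing, item discrimination differences, local dependence, missingness
patterns, or real DIF (slope and group-shift injections exist only as test
fixtures). Passing tests on simulated data therefore certify the
estimation and diagnostic machinery under the model, not robustness to the
violations real response data may carry.

## Problem sizes and determinism

The test suite and the reproduction script run the study at its native
size (300 persons × 10 items), averaging difficulty recovery over 20 seeds
and fit screens over 20 replicates; each calibration takes milliseconds,
so the whole suite completes in seconds. Property checks (Newton vs
grid-search likelihood oracle, type-I error of the DIF test under null
labels, RSM reduction) use fixed seeds and are fully deterministic.
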