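# raschkit

Dichotomous Rasch measurement for test and questionnaire data: joint
maximum-likelihood calibration of person abilities and item difficulties,
residual-based fit diagnostics, two-group differential item functioning
(DIF), Wright-map and KIDMAP person diagnostics, and A–E grading of person
measures. It is aimed at psychometric and health-measurement analysts who
want a scriptable, reproducible engine for the analyses that desktop Rasch
programs (the WINSTEPS family) perform interactively.

## The model

The dichotomous Rasch model places person ability θ and item difficulty δ
on one logit (log-odds) scale:

    P(X_ni = 1) = exp(θ_n − δ_i) / (1 + exp(θ_n − δ_i))

Raw scores are sufficient statistics, so estimation reduces to score
equations Σ_i P_i(θ_n) = r_n (and the dual for items), solved by damped
Newton–Raphson with step Δθ = (r − ΣP)/ΣPQ. Calibration alternates person
and item steps, centres difficulties at mean 0, applies the (L−1)/L JMLE
bias correction, and handles zero/perfect raw scores by a fractional
score-point adjustment (default 0.25) so that every person gets a finite
measure. Standard errors are 1/√(ΣPQ). Fit is screened with infit
(information-weighted) and outfit (unweighted) mean-squared standardized
residuals, plus an ability-stratum chi-square test along each item
characteristic curve. The rating-scale category-probability function is
included; with two categories it reduces exactly to the dichotomous model.

A seeded simulator generates the packaged study design: 300 simulees with
abilities from N(0, 1) answering 10 items at difficulties
−2.43 … 2.47 logits, plus one appended all-correct responder ("GPT301")
whose extreme score exercises the adjustment path.

## Worked example

```sh
raschkit study --seed 2 --out-dir reports
```

prints

```
GPT301: theta=4.74 logits, grade A, outfit=0.03
group ANOVA: F=2.09, p=0.15; reports in reports/
```

meaning: after calibrating the 301×10 simulated matrix, the all-correct
responder's adjusted measure is 4.74 logits — above the 3.0-logit cut, so
grade A — and its outfit mean-square of 0.03 is far below the 2.0 aberrance
screen (a perfect response string is entirely expected for so high a
measure). The gender-group ANOVA on person measures shows no difference,
as it should when labels are assigned at random. `reports/` contains
`items.tsv` and `persons.tsv` (measures, SEs, infit/outfit, ICC fit p,
grades), `dif.tsv` (per-item group contrasts with Wald 95% CIs), a
`kidmap.json`, and SVG renderings of the item display, DIF forest plot,
Wright map and KIDMAP.

The same pipeline is available as library calls (`simulate_responses`,
`jmle_calibrate`, `add_fit_statistics`, `dif_contrast`, `kidmap`,
`assign_grade`, ...) — see `docs/methods.md` for the statistical details.

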