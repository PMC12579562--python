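# Methods

This package implements a matched-cohort comparison of dual versus single
deceased-donor kidney transplantation and two resource-utilization analyses
built on it: a counterfactual projection of converting dual transplants to
singles, and a waitlist microsimulation. Real national-registry microdata is
not redistributable, so a calibrated synthetic registry generator stands in
for it; published summary values (volumes, hazard ratios, survival tables)
enter the projection directly as inputs.

## Synthetic registry generator

**What it emulates.** One row per transplant with donor, recipient, and
transplant covariates, two groups (dual / single), three time-to-event
endpoints, and binary secondary outcomes. Group sizes default to the study
scale (1,015 dual, 134,933 single).

**Case-mix structure.** Covariates are generated from a latent one-factor
Gaussian copula per block: a donor-quality factor and a recipient-risk
factor, each standard normal among singles and mean-shifted in the dual
group (donor shift 1.45 SD, recipient shift 0.70 SD). Every linked covariate
is a fixed, group-independent transform of `z = lambda * F + sqrt(1 -
lambda^2) * e`, so the dual-vs-single difference flows only through the
factors. Loadings are derived from the published group differences: exactly
for continuous medians (normal or log-normal maps) and binary proportions,
and by least squares on the latent thresholds for ordinal categories
(glomerulosclerosis — with "no biopsy" placed at the low end of the scale,
since dual donors are both biopsied more often and more sclerosed — sharing
breadth, dialysis-time group, HLA mismatch). The factor shifts are fixed by
rule at the smallest values compatible with all loadings <= 1, which
identifies each factor with its strongest-shifted covariate: KDRI (1.43 SD
on the log scale) for donors, recipient age (0.67 SD) for recipients. This
mirrors reality — dual allocation is driven by donor quality, and KDRI
essentially *is* the donor-quality score — and gives the groups the
realistic propensity overlap without which the published 3:1 matching
strategy could not have balanced. Nominal covariates with modest shifts
(renal diagnosis, race/ethnicity, induction, cPRA) keep exact group-specific
margins drawn from a correlated uniform.

**What is deliberately not reproduced.** Group-specific spreads (the dual
group inherits the single group's within-group scale, so e.g. the dual donor
age IQR is wider than printed); the full joint correlation structure of a
real registry; and the exact dual-group margins of linked ordinal categories
(least-squares approximations; `implied_margins()` reports the actual
targets, and the margin-convergence test checks against them). Passing tests
therefore show that the *analysis pipeline* is correct under a realistic
case-mix, not that the generator replicates registry microdata.

**Survival processes.** Graft failure and patient death are independent
exponential processes with constant baseline hazards 0.0374 and 0.0868
events/person-year, chosen so single-group six-year survival sits near the
published values (about 80% death-censored graft survival, 59% patient
survival). The dual-vs-single effect multiplies each hazard by a group
hazard ratio. Under this competing-risks structure the all-cause graft HR is
the baseline-hazard-weighted mean of the other two, so the three published
HRs (0.85 patient, 0.79 all-cause, 0.73 death-censored) cannot hold exactly
at once; the defaults pin the death-censored HR at 0.73 and the all-cause HR
at 0.79, implying a patient-survival HR of 0.816 (close to the printed
0.85). Administrative censoring is exponential at 0.15/year, capped at 9.3
years of follow-up. Event times use inverse-CDF draws from a fixed-order
stream, so configs differing only in effect sizes share their uniforms
(common random numbers). Secondary outcomes are Bernoulli at the published
group rates (DGF 39.3% / 31.7%; rejection observed only with sufficient
follow-up). BMI, cold ischemia time, and length of stay are set missing
completely at random at the published missingness rates (241, 203, 588 of
135,948).

## Cohort pipeline

Entry criteria are applied in a fixed order (adult recipient, deceased
donor, not en bloc, KDRI present, survival data present); a record failing
several rules is counted once, under the first. The order is a convention —
per-rule counts depend on it — and is part of the reported filter contract.
Imputation is single and deterministic: BMI by least squares on recipient
age, sex, and race/ethnicity (reference-coded indicators, first level as
reference); cold ischemia time on sharing breadth and distance; length of
stay by the observed median. Group comparisons use the tie-corrected
normal-approximation Wilcoxon rank-sum for continuous variables and the
Pearson chi-square without continuity correction for categorical ones. Note
a source inconsistency carried into the reference constants: the results
text states a 32.7% single-group DGF rate while the outcome table prints
964/3045 = 31.7%; the table value is used.

## Propensity matching

The propensity model is a maximum-likelihood logistic regression (IRLS,
tolerance 1e-10, up to 100 iterations) of dual-group membership on the
demographic covariates; perfect separation is detected and reported with the
offending covariate, and rank-deficient designs are rejected. Matching is
greedy k:1 nearest-neighbour without replacement on the *logit* of the
propensity score, processing treated units in descending score order
(hardest to match first) with seeded random tie-breaks and no caliper; all k
controls for one treated unit are taken before the next treated unit.
Balance is the standardized mean difference — difference in means over the
pooled-variance root for continuous covariates, the proportion analogue for
binary ones, and the maximum absolute per-level SMD for multi-level
categoricals. Ratio selection evaluates 1:1, 2:1, 3:1 and keeps the largest
ratio whose post-match max |SMD| stays within 0.1, recording every
candidate's balance; if none qualifies the best-balanced cohort is returned
flagged.

## Survival models

Kaplan-Meier curves (product-limit, right-continuous step interpolation at
query times) and the two-group log-rank test come from lifelines. Cox models
maximize the partial likelihood with the Efron tie correction (registry
follow-up is coarsely recorded); standard errors come from the observed
information, and intervals are Wald, `exp(coef +/- 1.96 se)`. A diverging
group coefficient (monotone likelihood) raises an explicit error. The
death-censored endpoint treats death with a functioning graft as censoring;
the all-cause endpoint is the first of graft failure and death. Per-year
survival tables report pointwise normal-approximation p-values from
Greenwood variances alongside the overall log-rank p — the published
per-year tables do not state which test their yearly p-values use, so the
pointwise comparison is a documented choice, not a reproduction.

## Counterfactual projection

With S the single-graft death-censored survival at the horizon and HR the
dual-vs-single hazard ratio, converting all n_dual dual transplants to
singles changes the surviving grafts from `n_dual * S^HR` (the
proportional-hazards transform of the single-graft curve — the only
transform consistent with the Cox model) to `2 * n_dual * S`; the percent
increase divides the difference by the successful single transplants
`n_single * S`. The horizon survival is log-linearly interpolated between
tabulated years (5 years falls between the published year-4 and year-6
values, 85.7% and 79.9%, giving S = 0.8275). Uncertainty is propagated by
evaluating at the HR confidence bounds only (no uncertainty on S), mirroring
the width of the published interval. With the published 2023 inputs (18,873
single, 184 dual, HR 0.73, CI 0.58-0.93) this reconstruction yields +144.3
grafts (139.7-150.2) and a 0.92% increase, rounding to the published 0.9%;
the published count of 140 (135-146) evidently used a slightly different
baseline-survival source, which is not stated, so the count is reproduced
approximately (the implementation documents its arithmetic and lands within
130-155) while the percent headline is reproduced exactly to the printed
precision. A "successful transplant" is a graft surviving death-censored at
the horizon, and a dual transplant counts as one transplant.

## Waitlist microsimulation

A closed cohort of 100,000 candidates is followed over 11 annual cycles
across three states (waitlist, transplanted, dead); transplanted and dead
are absorbing, and there are no arrivals. Each candidate-year consumes one
uniform draw tested against cumulative thresholds in the order death,
transplant, remain — the order is immaterial in expectation but fixes the
coupling. Path 2 (all duals performed as singles) inflates each year's
transplant probability by that year's dual-transplant fraction,
`p_tx' = min(1 - p_death, p_tx * (1 + dual_fraction))`: each converted dual
frees exactly one organ-equivalent transplant. With common random numbers
the pathways share draws, so Path 2 transplants occur no later and waitlist
deaths can only decrease, candidate by candidate. The historical yearly
transition probabilities are not public; the default schedule (transplant
0.15/year, death 0.05/year, dual fraction 0.01 ~ 184/19,057, optional
multiplicative jitter) is a stand-in, so the published "3% reduction in
waitlist deaths" is a reference point, not a test target — under the
stand-in schedule the model yields roughly a 0.5% reduction, and the figure
scales with the dual fraction and schedule shape. Correctness is instead
established against the closed-form Markov expectation
`N * sum_y p_death(y) * prod_{j<y}(1 - p_tx(j) - p_death(j))` and the
coupling monotonicity above.

## Numerical choices and test scales

Logistic and Cox convergence tolerances are 1e-10 and lifelines' defaults
(Newton with step-halving); matching tie-breaks add a seeded jitter of 1e-9
on the logit scale, far below meaningful score differences; SMDs with zero
pooled variance and unequal means report infinity. Test problem sizes are
chosen to keep the suite fast while leaving Monte-Carlo noise well below the
tested tolerances: margin convergence at n = 1e5, hazard-ratio recovery on
50 replicates of the 1,015/3,045 matched-cohort size, microsimulation
analytics at n = 1e5 and coupling over 100 seeds, and matching-oracle
equality on all random instances of <= 12 units plus one full-scale
(135,948-record) balance run.

## Limitations

Margins, not joint structure, are calibrated; hazards are constant over
time (a piecewise shape would better track the published per-year tables);
the projection treats S as fixed when propagating uncertainty; the
microsimulation has no arrivals, no allocation-priority structure, and no
post-transplant states; and the published per-year survival p-values and the
exact arithmetic behind the published additional-transplant count are
reconstructed, not reproduced.
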