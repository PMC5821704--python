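# Methods

## Outcome and predictors

The outcome is binary non-satisfaction one year after primary total knee
replacement: the five-level answer to the overall-satisfaction question is
collapsed so that *very* and *somewhat satisfied* map to 0 and *neither*,
*somewhat* and *very dissatisfied* map to 1. Twelve pre-operative candidate
predictors are coded against fixed reference categories: sex (woman ref.),
age at operation in raw years (uncentred — the published equation multiplies
raw age), higher education, BMI ≥ 35 kg/m², osteoarthritis vs RA/other,
comorbidity count, treated anxiety, treated depression, current smoking,
intra-articular corticosteroid injection, surgeon experience (≥ 8 training
years), and the pain/function score. The comorbidity count enters the
candidate pool as a single ordinal 0–3 (no per-level coefficient is published
and four dummies would burn events); dummies against reference 0 are kept for
descriptive tables.

The development instrument (Oxford Knee Score, 0–48) and external instrument
(WOMAC) differ, so only the within-cohort standardised score
`z = (x − x̄)/s` crosses cohorts; lower values mean worse pain and function.
Each cohort's own complete-case mean and sample SD (ddof = 1) define the
scale and are reported so the transform can be inverted. No points-to-points
conversion between instruments is attempted.

## Exclusion cascade

Raw registry extracts are filtered in a fixed order — keep primary TKR, drop
the thirteen outcome-masking diagnoses (multiple sclerosis … poliomyelitis),
keep one-year follow-up completers, drop patients without a satisfaction
answer — and a log records the count removed at each step; the removed counts
plus the analysable count always sum to the raw count. The synthetic raw
extracts reproduce the published cascade *exactly* by construction
(development: 1616 → 845 primary → 738 → 523 → 450). The external registry's
printed arithmetic is internally inconsistent (808 completers − 16
non-responders = 792, yet 791 analysed; per-operation counts sum to 1540, not
the printed 1654): the fixture targets the analysed 791 by marking 17
completers as non-responders and uses the per-type counts; the discrepancy is
documented here rather than resolved.

## Synthetic cohorts

With no public data, the generator emulates the two registries from their
published summaries: binary predictors are drawn **independently** at the
printed marginal prevalences (denominators excluding missing), age and raw
score from truncated normals at the printed mean/SD and ranges (age 70 ± 8 on
28–90 and score 20 ± 8 development; 72 ± 9 on 22–92 and 21 ± 8 external), and
the outcome Bernoulli from the published logistic equation applied to the
coded row (score standardised within the generated cohort, matching the
analysis). Per-variable missingness is injected afterwards, MCAR by default,
at rates recovered from the printed per-variable denominators (development:
education 16.2 %, surgeon experience 13.1 %, score 9.6 %, others ≤ 10 %;
external: education 25.0 %, score 18.8 %, smoking 1.3 %); sex, age and BMI
are never blanked. A MAR mechanism with logistic dependence on the
always-observed age and sex (intercept solved so the marginal rate is exact)
is available so imputation assumptions hold by construction.

What the generator does **not** emulate: inter-predictor correlation (only
marginals are published; a Gaussian-copula hook exists but defaults off),
hospital-level clustering beyond a two-level hospital label, and any
selection into the registries. Consequently a passing suite shows the
*procedures* behave correctly under known truth, not that real-data
performance numbers are reproduced. Two consequences are worth naming. First,
the printed external (re-estimated) equation implies a mean risk of ~6 % at
the external case mix, far below the observed 19.9 % — likely a misprinted
intercept in the source; the generator uses the printed coefficients as
given, so synthetic external cohorts have ~6 % prevalence. Second, current
smoking (prevalence 4.4 %, coefficient 0.93) has too little information at
n = 450 for 60 % bootstrap retention, so the synthetic development cohorts
retain anxiety, steroid and the standardised score much more often than
smoking — on the real data its retention presumably rode on correlations the
independence design cannot carry.

## Multiple imputation

Chained equations, m = 50 by default, 10 cycles per chain, variables visited
in order of increasing missingness, each chain independently seeded from the
master seed and started from a random draw of observed values. Per-variable
models: Bayesian logistic draws for binary indicators (coefficients drawn
from the approximate normal posterior of a GLM fit, values drawn Bernoulli),
Bayesian linear draws for the standardised score (variance from a scaled
inverse-chi-squared draw), and a linear draw rounded and clipped to 0–3 for
the ordinal comorbidity count. Every imputation model includes all other
candidate predictors, the outcome, and — for the multi-centre development
cohort only — hospital dummies as an auxiliary; the single-centre external
registry has no such variable. Predictive-mean matching and multilevel
structures are deliberately out of scope. A degenerate per-variable fit
(e.g. perfect separation on a small chain) falls back to a marginal
Bernoulli draw rather than aborting the chain. The imputed standardised
score is back-transformed to the raw scale so completed tables have no holes.

Rubin's rules pool per-imputation fits: pooled coefficient = mean; pooled
covariance `T = W + (1 + 1/m)B` with `W` the mean within-imputation
covariance and `B` the between-imputation covariance of coefficients;
per-coefficient degrees of freedom `(m − 1)(1 + W/((1+1/m)B))²`, infinite
when `B = 0`. The source's looser wording ("standard error average plus the
variability between imputations") is read as the canonical formulas it cites.

## Selection

Backward elimination refits the logistic model and removes the non-forced
predictor with the largest Wald p-value while it exceeds α = 0.157 (the AIC-
like threshold recommended for prognostic modelling), one at a time; sex and
age are forced regardless of significance; exact p-value ties drop the
candidate latest in the declared order, making the procedure deterministic.
The bootstrap wrapper draws, per replicate, n patients with replacement and
attaches each patient's values from one completed dataset chosen uniformly
at random — replicates keep the original sample size and within-patient
coherence; a stacked-row sampling mode exists for sensitivity analysis.
Inclusion frequencies are retention fractions over B = 200 replicates
(forced predictors are 1 by construction); the final model takes every
candidate at ≥ 60 %. Degenerate replicates (e.g. a one-class outcome after
resampling) are dropped and counted, with failure if more than 10 % drop.

## Fitting, discrimination, calibration, optimism

Logistic models are fit by iteratively reweighted least squares (tolerance
1e-8), covariance from the observed information. Degenerate design columns
receive minimum-norm coefficients with enormous standard errors — which
backward elimination then removes — while genuine separation (non-convergence
or |β| > 50, or statsmodels' perfect-prediction signal) raises an error
naming the separating predictor where identifiable. One-class outcomes and
missing cells are errors, and prediction never imputes silently.

AUC is the Mann–Whitney concordance computed from midranks; tied predictions
count ½ per case–control pair. The apparent AUC of a multiply-imputed cohort
is the mean over imputations of the pooled model's AUC (median reported
alongside), since no pooling rule for AUCs is prescribed anywhere.

Calibration ranks patients by predicted risk into 10 near-equal groups
(sizes differ by at most one; any remainder fills from the lowest bin; tied
predictions stay together, so heavy ties can unbalance bins — noted in the
output). Each bin reports mean predicted risk, observed proportion x/n and
the 95 % Agresti–Coull interval: ñ = n + z², p̃ = (x + z²/2)/ñ,
p̃ ± z√(p̃(1−p̃)/ñ), clipped to [0, 1]. The calibration plot shows observed
event proportion per decile (the source figure's "actual mean score" axis is
not fully defined; observed proportion is the defensible reading).

Internal validation: B = 200 replicates resample patients with replacement
(one imputation per replicate), re-run the selection, refit, and compare the
replicate model's AUC on its own sample with its AUC on the original;
optimism is the mean excess and `AUC_corrected = AUC_apparent − optimism`
holds exactly. Re-running the *entire* 200-replicate frequency selection
inside each validation replicate would cost B² selection runs for no
qualitative change in the optimism estimate; repeating the selection
*procedure* as a single backward elimination per replicate is the standard
honest-validation compromise and the default here (a fixed-model mode
mirrors the literal frozen reading). Replicates that fail to converge are
dropped and counted; > 10 % failing is an error.

## Transport and re-estimation

Transport applies the frozen development coefficients unchanged to the
external cohort — its score standardised with the external cohort's own
mean/SD (a mode reusing the development scale exists for sensitivity) — and
reports the AUC averaged over external imputations plus a calibration table;
the frozen fit is never mutated. Re-estimation fits exactly the same
predictor list on each external imputed dataset (no re-selection) and pools
by Rubin's rules, yielding setting-specific coefficients, odds ratios and
CIs, and the re-estimated AUC. No intermediate updating (intercept
recalibration, slope shrinkage) is implemented: the comparison is deliberately
frozen-vs-refit.

## Cohort comparison

Case mix is compared with the uncorrected chi-squared test for categorical
variables (continuity correction available but off — consistent with the
printed satisfaction contrast) and Welch's unequal-variance t-test for
continuous ones; denominators exclude missing values and percentages round
half-up to one decimal. One printed value resists reproduction: 157/791 is
19.8 % at one decimal, not the printed 19.9 % (every other printed
percentage checks out under half-up rounding); the descriptive report states
19.8. The printed age p-value (0.01) is likewise smaller than the rounded
means/SDs imply; neither is chased.

## Problem sizes and seeds

Production defaults are the published m = 50 and B = 200. The analysis
drivers use m = 10 and the test suite smaller m/B (and cohort sizes from 450
up to 100 000 for asymptotic checks) — sizes chosen so each property is
comfortably identified at its stated tolerance. Every stochastic stage takes
an explicit seed (the run configuration refuses to start without one), child
seeds derive from a master generator, and repeated runs of the same
configuration are bit-for-bit identical, including SVG output.

## Known limitations

Independence of generated predictors (above) is the biggest gap to real
registry data; the external equation's implausible intercept is inherited
from the source; the development cohort's 64 events are below common
events-per-variable guidance, which is precisely why the optimism correction
matters; and calibration beyond deciles (smoothed curves, recalibration
slopes) is out of scope.
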