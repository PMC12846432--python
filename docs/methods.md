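# Methods

## Trial data model

A hut-night record stores the full location × fed × dead cross-
classification (12 non-negative integer cells) even though the
standard endpoints only use its margins: the finer grid is a lossless
superset that the simulator and any future endpoint (e.g. fed-and-dead
rates) can draw on. `exited` is the sum of the veranda- and
window-trap cells; `dead` counts mosquitoes killed in any location —
mortality is defined without a location qualifier. Night indices are
trial-global (1…N); the rotation period length is a parameter
(default 7 nights, one period per week). The Latin-square check
verifies three balance properties on recorded data: one arm per hut
per period, one hut per arm per period, and no (hut, arm) repeat
within a complete block of `n_arms` periods. Blocks left incomplete
at the end of a trial are not checked for the third property.

## Endpoints

Point estimates are crude proportions of pooled counts; the default
95% CI is Wald on the proportion scale truncated to [0, 100], with
Wilson available behind a flag. Wald is the default because it is
what published hut-trial tables print; the bundled published CIs match
it to within one decimal (the published tables truncate rather than
round the last digit, so comparisons at the second decimal are not
meaningful). Relative endpoints can be negative — a treated arm can
attract or feed more than control — and are reported as-is, never
floored at zero: the washed standard-comparator arm in the bundled
data caught 89.6% *more* than control, and flooring would hide it.

Blood-feeding inhibition (rate-based) and personal protection
(count-based) coincide exactly when both arms caught equal numbers;
otherwise they answer different questions and both are reported.

The per-night catch row of published tables is labelled a geometric
mean but equals total/nights arithmetically; the summary table
therefore reports the arithmetic mean and labels it as such, with the
Williams-style geometric mean (`exp(mean log(c+1)) − 1`, needing the
nightly counts) available as an option.

## GLM engine

Proportional outcomes (died, fed) are modelled as binomial counts per
hut-night with a logit link; nightly totals as Poisson with a log
link. Covariates are treatment arm, hut and bait as reference-cell
coded categorical fixed effects. The published analysis mentions both
mixed-effects and hut/bait-adjusted regression; this package fits
**fixed** hut and bait effects with a **cluster-robust variance over
hut-nights**, which is exactly reproducible without a random-effects
integrator and matches the published decision tables' arithmetic.
Full integrated-likelihood random-effects fits are a non-goal.

Fitting is by IRLS: convergence when the relative deviance change
falls below 1e-8, at most 50 iterations, with step-halving whenever a
step would increase the deviance (so the deviance path is
non-increasing by construction). Hut-nights with zero catches carry
no binomial information and are dropped from the design. Separation
(a factor level whose pooled outcome is all-0 or all-1) is detected
before fitting and reported as a warning plus a flag on the fit; the
coefficient is reported where IRLS stops rather than penalised (no
Firth correction).

The robust covariance is the clustered sandwich
`A⁻¹ B A⁻¹ · G/(G−1)` with `A = X'WX`, B the outer product of
cluster-summed score contributions `x_i(y_i − μ_i)`, and G the number
of hut-night clusters. The `G/(G−1)` factor is the plain
cluster-count correction; other implementations additionally scale by
`(n−1)/(n−k)` (the regression-df convention), which the test suite
accounts for when cross-checking against statsmodels. With aggregated
binomial rows, one hut-night is one record, so each cluster holds one
observation; clustering still matters because the variance is then
robust to extra-binomial variation within hut-nights.

Treatment contrasts are returned on the odds-ratio scale,
`OR = exp(β_cand − β_ref)`, with the CI and two-sided p from the
delta method on the log scale using the robust covariance.

## Non-inferiority

The WHO absolute margin δ (default 0.07) is converted to the
odds-ratio scale at the comparator's proportion π₀:
`NIM = odds(π₀ − δ)/odds(π₀)` for mortality (NIM < 1, higher kill
favours the candidate) and `odds(π₀ + δ)/odds(π₀)` for blood feeding
(NIM > 1, lower feeding favours the candidate). π₀ is the
comparator's **crude pooled proportion from counts**; under this rule
all eight single-arm margins and both pooled blood-feeding margins in
the bundled published tables reproduce to the printed two decimals.
The two pooled *mortality* margins printed in the source tables (0.68
and 0.72) do **not** reproduce from crude pooled proportions (which
give ≈0.75/0.76); the publication does not state the variant rule it
used there, and this package deliberately does not guess at one — it
implements the crude-proportion rule uniformly and documents the
discrepancy here.

Decision rules: non-inferior iff the OR CI bound strictly clears the
margin (lower bound > NIM for mortality; upper bound < NIM for blood
feeding); a bound exactly on the margin is conservatively *not*
non-inferior. Superiority is declared from the two-sided p < α
(default 0.05) with the point estimate on the favourable side of 1 —
from p rather than from the rounded CI excluding 1, because a CI
printed as touching 1.00 can coexist with p < 0.05.

Pooled (unwashed + washed) comparisons relabel the candidate pair and
reference pair to single treatment levels and refit the adjusted
model on the records of those four arms only, keeping hut/bait
adjustment and hut-night clustering; whether the source analysis kept
the other arms in the model is not stated, and the subset fit was
chosen as the cleaner two-level contrast.

## Bioassays

Tube tests: mortality at 24 h over pooled replicates; Abbott's
correction `100·(t − c)/(100 − c)` applied when control mortality is
in [5%, 20%), identity below 5%, test invalid at ≥20%. Because
published summaries sometimes print raw mortality even with control
mortality in the correction band, both raw and corrected values are
always reported, with displays defaulting to raw. Classification:
≥98% susceptible, 90–97% possible resistance, <90% resistant
(boundaries inclusive of the upper class).

Cone assays: percentages pooled over replicates (equivalently, the
exposure-weighted mean of per-replicate percentages); the WHO
bio-efficacy criterion is met when mortality ≥80% **or** knockdown
≥95%. The inclusive ≥ is used because a net inducing exactly 80%
mortality is described in the WHO framework as meeting the cut-off.
The replicate-level Wald CI can exceed [0, 100] with few replicates;
the untruncated bounds are retained (truncation is a display choice).

## Chemical durability

Retention `100·Cn/C0` and the per-wash wash-resistance index
`100·(Cn/C0)^(1/n)` (default n = 20 washes) satisfy
`retention = 100·(WRI/100)^n` exactly and are scale-invariant in the
content units. A washed content of zero leaves the index undefined
(per-wash log-loss infinite) and raises. Published retention values
can differ from ratios of published contents by ±0.1 points because
lab values were rounded before printing; the wash-resistance indices
reproduce exactly to the printed decimal. Surface dose conversion:
g/kg × g/m² = mg/m². The WHO content check is
|measured − declared|/declared ≤ 25%.

## Synthetic trial generator

The generator emulates the study conditions the analysis assumes: 7
arms in 7 huts, weekly Latin-square treatment rotation (a random
cyclic square with rows, columns and symbols independently permuted
under the seed; tiled cyclically when rounds exceed arms), daily
cyclic bait rotation (an independent Latin structure at the nightly
scale, with no claim of orthogonality to the treatment square).
Nightly entries per hut are negative binomial with mean
μ · hut_effect · bait_effect · deterrence and dispersion k
(variance μ + μ²/k); each entering mosquito is assigned dead, fed and
exited by independent Bernoulli draws (exited split 50:50 between
veranda and window), assembled in one 12-cell multinomial draw. A
joint fed × dead 2×2 option exists for sensitivity analyses; the
default is independence because the analysis only ever uses margins.

Defaults are the published trial's magnitudes: per-arm exit/feed/kill
probabilities and deterrence multipliers from the bundled totals,
baseline entry mean 374/112 ≈ 3.3 per hut-night, 16 rounds of 7
nights (112 nights per arm, matching the published per-arm night
count), hut and bait multipliers of 1, and dispersion k = 1 — a
strong night-to-night overdispersion typical of hut catches (the
source does not report its dispersion). What the generator does *not*
emulate: seasonal and weather-driven entry trends, hut-to-hut
behavioural carryover, net-replicate (within-arm) variation, and
correlation between feeding and dying induced by net contact — so
passing tests show the *analysis* is correct under the stated
sampling model, not that real trials satisfy that model.

Seed handling: one master seed; per-replicate generators are spawned
from a `SeedSequence`, so power estimates are reproducible and
replicates independent. The full pipeline
(simulate → CSV → read → analyse) is byte-identical under a fixed
seed.

Power for a non-inferiority comparison is the fraction of simulated
trials whose verdict is non-inferior or better, with a Wilson binomial
CI. With the candidate's true kill probability exactly δ below the
reference's, the conclusion rate collapses towards the test's α level
— the boundary property that validates the procedure.

## Problem sizes in the test suite

Simulation-backed checks run at 7 rotation rounds (49 nights per arm,
343 hut-night records) — large enough for stable GLM fits while
keeping the suite fast: 200 replicates for CI coverage (asserted
within ±4 points of 95%), 60 replicates for the power boundary check,
60 for homogeneity calibration. The law-of-large-numbers check uses
an inflated entry mean (μ = 250) so that binomial noise is well below
the 2-point tolerance.

## Known limitations

- No random-effects (integrated likelihood) or Bayesian fits.
- Adjusted odds ratios from the source trial cannot be re-derived
  without its nightly raw data (unreleased); only direction,
  significance and synthetic-data recovery are checked.
- The pooled-mortality margin discrepancy described above.
- Wald intervals degenerate at 0/100% proportions; use Wilson there.
- The simulator's independence assumptions listed above.
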