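# Methods

## The decision problem

For early breast cancer, breast-conserving surgery (BCS, with
radiotherapy) and mastectomy (MST, with or without reconstruction) have
equivalent survival, so the package compares them on expected health-state
utility — a single-index quality-of-life weight on [0, 1] — rather than
quality-adjusted life years. The BCS arm is a lottery over good and poor
cosmetic result; the MST arm is a lottery over reconstruction. Collapsing
both chance nodes gives

    EU_BCS(p) = p·u_good + (1 − p)·u_poor
    EU_MST    = q·u_recon + (1 − q)·u_only

with `p` the model-predicted chance of good cosmesis and `q` the
reconstruction probability. The decision rule is the harm/benefit
treatment threshold `P* = harm/(harm + benefit)` with
`benefit = u_good − EU_MST` and `harm = EU_MST − u_poor`; BCS is preferred
when `p > P*`. The model assumes the utility ordering
`u_good > EU_MST > u_poor`; any configuration violating it is rejected
with the violated inequality named (both benefit and harm must be positive
for a threshold to exist).

## Cosmesis prediction model

`logit P(good) = β₀ + β₁·(TV/BV) + γ_loc`, with the TV/BV ratio on the
×1000 scale (tumor cm³ / breast cm³ × 1000) and upper-lateral as the
reference location. `β₁` is constrained negative: a relatively larger
excision can only worsen the expected cosmetic result.

The originating study published only derived quantities of its fitted
model: five per-location ratio cut-offs at the 35.8% threshold
(21.6 / 15.1 / 4.1 / 3.2 / 14.7) and one worked-example prediction (71% at
upper-medial, ratio 5.6). These six constraints are linear in the six
unknown coefficients on the logit scale, so
`calibrate_from_printed_values` recovers the coefficients exactly with a
6×6 solve:

    intercept  2.7797   ratio_coef  −0.1557
    γ upper-medial −1.0122   lower-lateral −2.7253
    γ lower-medial −2.8654   central       −1.0745

Before freezing these as the versioned default
(`data/derived_model.yaml`), the solution was cross-validated against two
published probabilities *not* in the constraint system: ≈10% at
lower-lateral ratio 15 (model: 9.3%) and ≈60% at upper-lateral ratio 15
(model: 60.9%). The derived values inherit the rounding of the published
cut-offs; residual discrepancy from the authors' unpublished coefficients
cannot be excluded.

Two thresholds coexist deliberately. The published cut-off row was
computed at the headline 35.8%, so cut-off reproduction uses 0.358 (kept
in the config's `calibration` block); recomputing `harm/(harm+benefit)`
from the three-decimal published utilities gives 0.3538, and that value is
what `treatment_threshold` returns and what recommendations use. The
0.4-point gap is rounding in the published utilities, not a model
difference.

Intercept updating (`update_intercept`) shifts the intercept by
`logit(new prior) − logit(old prior)`, leaving all covariate effects — and
therefore every between-patient odds ratio — unchanged. The original
analysis raised the prior "slightly (2%)" above the observed 71.0%
prevalence to compensate for unobservable false negatives; we read this as
+2 percentage points (0.710 → 0.730, a shift of +0.0992 log-odds) but keep
both priors explicit arguments, since a relative reading (×1.02) is also
defensible.

## Panel scoring

Cosmesis is a panel judgement: each rater scores 11 items on a 0–3 scale
(0 = excellent … 3 = poor) and the unweighted mean over all non-missing
(rater, item) cells is dichotomised at 1.5, *inclusive* — a mean of
exactly 1.5 is a good result. Raters are equally weighted regardless of
profession, missing cells are dropped from the mean (complete-case over
cells), and the per-photograph structure of the original questionnaire is
treated as already merged into one item score per rater. These are the
simplest conventions consistent with an "average of all items and panel
members" rule; none of them affect the decision model itself.

## Utilities

The default utilities (0.908 / 0.843 / 0.859 / 0.876) are the published
point estimates. The reconstruction probability is not printed anywhere;
the default 7/17 ≈ 0.412 is back-solved from the pooled MST utility
(0.866 = q·0.876 + (1 − q)·0.859) and is overridable in config.

`anchored_bcs_utilities` implements the anchoring construction: the
good/poor deltas are taken relative to the *pooled* cohort mean and added
to an external large-sample BCS anchor, the unique convention under which
the prevalence-weighted recombination of the two outputs returns the
anchor exactly. Instrument-to-utility conversion is a plain affine map
with optional clamping to [0, 1]; the published crosswalk coefficients
(EORTC QLQ-C30 and FACT-G to EQ-5D) are literature values and must be
supplied in config — none are bundled, and tests use synthetic
coefficients.

## Uncertainty analysis

All parameters live on [0, 1], so uncertainty is beta, parameterised by
mean and standard error via the method of moments
(`ν = m(1−m)/se² − 1`, `α = mν`, `β = (1−m)ν`), which requires
`se² < m(1−m)`. A standard error of exactly 0 is admitted as an explicit
point mass so a fully degenerate analysis collapses to the deterministic
base case; `beta_from_moments` itself still rejects non-positive standard
errors.

`run_psa` draws all parameters independently (no correlation structure is
specified anywhere) in a fixed declared order from one seeded generator,
so results are bit-reproducible per seed. The reference patient is the
published "average" case (upper-medial, ratio 5.6). The predicted
probability of good cosmesis is held fixed by default and can be given its
own beta distribution via `p_good_se`. EVPI is the mean opportunity loss
of the baseline-optimal arm, `E[max(EU_BCS, EU_MST) − EU_baseline]`, which
equals `mean(max) − max(mean)` when the baseline is the arm with the
higher mean; tests verify the identity on every run.

The default standard errors in `data/default_config.yaml` (0.020 / 0.040 /
0.012 / 0.012 utilities, 0.050 reconstruction rate) are this package's
choices: the original distribution parameters were never published, and
these reflect the relative source sizes (the BCS utilities rest on 61
respondents split 44/17, the MST utilities on 485). The original headline
PSA outputs (share of samples favouring BCS, EVPI per patient) therefore
cannot be reproduced numerically and are covered only by qualitative and
identity checks.

## Synthetic cohorts

`generate_cohort` emulates the published cohort summaries, not its raw
data (which were never released): locations are categorical with the
published mix (47.8 / 20.3 / 18.8 / 4.3 / 8.7%), the TV/BV ratio is
log-normal matched to the published median 2.47 and IQR 1.25–5.54
(log-sd = (ln 5.54 − ln 1.25)/(2·0.6745) ≈ 1.104 — log-normal is the
minimal strictly-positive, right-skewed choice consistent with
median ≪ mean), outcomes are Bernoulli draws from the logistic model
itself, panel means are generated label-first (centre of the label's score
interval, 0.75 or 2.25, plus truncated Gaussian noise of sd 0.4, so label
and score can never disagree), and QoL is the state utility plus clamped
Gaussian noise (sd 0.02). Breast volumes are uniform on 200–1500 cm³
purely to make volumes concrete; only the ratio enters the model. Ratios
are capped at 1000 (a tumor cannot exceed its breast).

What passing tests show, and don't: the generator reproduces the marginal
summaries and the model-implied outcome process, so it validates the
arithmetic and the estimation machinery (the refit's ~95% CI coverage, the
1/√n error decay, AUC/PPV/NPV behaviour). It does not reproduce
between-rater disagreement, real breast-volume anatomy, model
misspecification, or measurement error in volumes — agreement on
synthetic data says nothing about the model's clinical validity.

`fit_logistic` delegates the maximum-likelihood fit to statsmodels' Newton
solver (tolerance 1e−10) and surfaces perfect separation and
single-class inputs as explicit errors. Refits are returned as plain
coefficient/SE tables rather than model objects, since a refit may
legitimately estimate a non-negative ratio slope.

## Numerical and interface choices

- Classification at a threshold is strict (`p > threshold` ⇒ positive);
  equality is negative. Arm comparison treats `|EU_BCS − EU_MST| ≤ 1e−12`
  (configurable) as indifferent, because at the threshold the arms are
  equal by construction.
- When indifference arises from fully degenerate utilities (benefit and
  harm both zero) no threshold exists; `recommend` reports `nan` for it
  instead of raising, while a decisive margin with an ordering violation
  still raises.
- Ratio cut-offs outside (0, 1000] are returned as-is and flagged by the
  CLI as "outside realisable range": they mean BCS is always (≤ 0 never
  reaches the threshold going down) or never preferred, and clamping would
  hide that.
- AUC is the rank-based Mann–Whitney statistic with average ranks, i.e.
  ties count ½; tests check it against an O(n²) pair-counting oracle.
- Config is one YAML file with a versioned schema; unknown keys are
  rejected by name. The shipped defaults reproduce the published values
  and are labelled study defaults.

## Problem sizes used in the test suite

Monte-Carlo checks use cohorts of 10,000 for distributional summaries,
100 replicates of n = 2000 for CI coverage of the refit, 10,000 draws for
PSA seed-stability, and 10,000 random utility sets for the
threshold-indifference identity; these sizes put Monte-Carlo error well
inside the asserted tolerances while keeping the default run fast.

## Known limitations

- The derived default coefficients are exact consequences of *rounded*
  published numbers, not the original fit.
- The original AUC (0.827) cannot be recomputed without the per-patient
  data; only the AUC algorithm is verified.
- No costs, no survival differences, no EVPPI, no neo-adjuvant or
  oncoplastic alternatives, and no time-discounting: the model compares
  long-term QoL only, as the underlying analysis did.
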