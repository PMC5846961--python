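# bcsdecision

A decision-analysis package for the choice between **breast-conserving
surgery (BCS)** and **mastectomy (MST, with or without reconstruction)** in
early breast cancer, aimed at methodologists and clinical researchers
working on surgical decision aids. Overall survival is equivalent between
the two operations, so the comparison reduces to expected quality of life
(QoL), which hinges on the cosmetic result of BCS.

## The model

Each patient is described by the tumor-volume/breast-volume ratio
(TV/BV = tumor cm³ / breast cm³ × 1000) and the tumor location (four
quadrants or central). A logistic model gives the chance of a good
cosmetic result after BCS:

    logit P(good) = β₀ + β₁·(TV/BV) + γ_location        (γ_upper-lateral = 0)

The four terminal health states carry EQ-5D-compatible utilities *u*: BCS
with good cosmesis (0.908), BCS with poor cosmesis (0.843), mastectomy only
(0.859), mastectomy with reconstruction (0.876); the two MST states pool to
0.866 with a reconstruction probability of 7/17. Comparing the two arms'
expected utilities yields the classic harm/benefit treatment threshold
(Pauker–Kassirer):

    benefit = u_good − u_MST = 0.042      harm = u_MST − u_poor = 0.023
    P* = harm / (harm + benefit) ≈ 0.354

BCS is preferred exactly when P(good) exceeds P*, which inverts to one
TV/BV ratio cut-off per tumor location (21.6 / 15.1 / 4.1 / 3.2 / 14.7 for
upper-lateral / upper-medial / lower-lateral / lower-medial / central at
P* = 0.358). The published coefficients of the logistic model were never
released, so the shipped defaults are reconstructed exactly from those six
published constraints by a linear solve (see `docs/methods.md`).

A probabilistic sensitivity analysis places method-of-moments beta
distributions on every parameter, redraws them jointly, and reports the
probability each arm is optimal plus the expected value of perfect
information (EVPI). A synthetic-cohort generator mirroring the original
69-patient study's summary statistics makes every stage testable, and a
maximum-likelihood refit supports parameter-recovery studies.

> The shipped defaults are study-, surgeon- and panel-specific estimates;
> validate them before any clinical use.

## Worked example

A patient with a 3.8 cm³ upper-medial tumor in a 675 cm³ breast:

```
$ bcsdecision recommend --tumor-volume 3.8 --breast-volume 675 --location upper_medial
TV/BV ratio:        5.63
P(good cosmesis):   0.709
EU(BCS):            0.8891
EU(MST):            0.8660
Threshold:          0.3538
Recommendation:     BCS
```

The TV/BV ratio is 5.6; the model predicts a 71% chance of good cosmesis,
well above the 35.4% threshold, so BCS offers the higher expected QoL
(0.889 vs 0.866 on the utility scale). The per-location cut-off table and
the harm/benefit arithmetic:

```
$ bcsdecision cutoffs
Ratio cut-offs at P = 0.358:
     upper_lateral:   21.6
      upper_medial:   15.1
     lower_lateral:    4.1
      lower_medial:    3.2
           central:   14.7

$ bcsdecision threshold
Benefit:   0.042
Harm:      0.023
Threshold: 0.3538 (35.4%)
```

Other subcommands: `graph` (decision grid as TSV), `psa` (probabilistic
sensitivity analysis), `simulate` (synthetic cohort CSV), `evaluate`
(AUC/confusion diagnostics on a cohort), `report` (everything as JSON or
text). All accept `--config` for a YAML file overriding the defaults in
`src/bcsdecision/data/default_config.yaml`.

The same functionality is available as a library:

```python
from bcsdecision import (PatientPresentation, TumorLocation, recommend,
                         default_model, default_utilities)

patient = PatientPresentation(3.8, 675.0, TumorLocation.UPPER_MEDIAL)
result = recommend(patient, default_model(), default_utilities())
print(result.recommendation, round(result.p_good, 3))   # BCS 0.709
```

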