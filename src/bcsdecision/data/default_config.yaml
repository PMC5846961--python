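# Study defaults — validate before clinical use.
# Utilities are the published health-state point estimates; p_recon is the
# reconstruction rate back-solved from the pooled mastectomy utility
# (0.866 = p * 0.876 + (1 - p) * 0.859  =>  p = 7/17).
schema_version: 1

utilities:
  u_bcs_good: 0.908
  u_bcs_poor: 0.843
  u_mst_only: 0.859
  u_mst_recon: 0.876
  p_recon: 0.4117647058823529

# Coefficients are re-derived at load time from the six published
# constraints; data/derived_model.yaml holds the frozen result.
model: derive-from-printed
calibration:
  threshold_prob: 0.358
  cutoffs:
    upper_lateral: 21.6
    upper_medial: 15.1
    lower_lateral: 4.1
    lower_medial: 3.2
    central: 14.7
  anchor:
    location: upper_medial
    ratio: 5.6
    probability: 0.71

# Instrument-to-utility maps are literature coefficients and must be
# supplied by the user; none are bundled.
maps: []

# Reference ("average") patient for the PSA: the published worked example.
reference_patient:
  tumor_volume_cm3: 3.8
  breast_volume_cm3: 675.0
  location: upper_medial

psa:
  n: 10000
  seed: 0
  # Standard errors of the beta distributions.  The source study did not
  # publish them; these defaults reflect the relative cohort sizes (the
  # BCS utilities come from 61 patients, the mastectomy utilities from 485).
  standard_errors:
    u_bcs_good: 0.020
    u_bcs_poor: 0.040
    u_mst_only: 0.012
    u_mst_recon: 0.012
    p_recon: 0.050

tolerances:
  indifference: 1.0e-12
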