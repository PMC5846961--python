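# Versioned derived-default coefficients of the good-cosmesis logistic model.
# Reconstructed (version 1) by calibrate_from_printed_values from the six
# published constraints: the five per-location ratio cut-offs at P = 0.358
# (upper_lateral 21.6, upper_medial 15.1, lower_lateral 4.1,
# lower_medial 3.2, central 14.7) and the worked-example anchor
# (upper_medial, ratio 5.6, P = 0.71).  Do not edit by hand; re-derive.
version: 1
coefficients:
  intercept: 2.7797226058510143
  ratio_coef: -0.15573045940464236
  offset_upper_medial: -1.0122479861301756
  offset_lower_lateral: -2.7252830395812415
  offset_lower_medial: -2.86544045304542
  offset_central: -1.0745401698920325
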