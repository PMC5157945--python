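band_concentration: 33.0
cdn_weight: 0.0
cin_divides: true
cin_gain_broad: 0.4
cin_gain_narrow: 1.5
coherences:
- 0.016
- 0.064
- 0.128
- 0.256
- 0.512
- 1.0
component_directions:
- 0.0
- 135.0
cued_direction: 0.0
exponent: 1.5
gain_broad: 0.3
gain_narrow: 0.35
kappa_broad: 0.5
kappa_narrow: 15.0
n_points: 360
norm_constant: 0.06
rf_feature_sigma: 37.0
scale: 1.55
supp_feature_sigma: 180.0
variant: cin
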