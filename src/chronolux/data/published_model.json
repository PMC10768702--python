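{
 "version": 1,
 "description": "Frozen published two-component linear model for the normalized mean time-of-day rating (4-point merged scale divided by 7).",
 "predictors": ["PC1", "PC2"],
 "intercept": 0.583,
 "coefficients": [0.034, 0.017],
 "r2": 0.760,
 "adjusted_r2": 0.755,
 "aic": -221.675,
 "selected": true,
 "n": 104
}
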