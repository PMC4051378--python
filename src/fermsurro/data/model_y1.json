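{
  "response_name": "Y1",
  "response_scale": "fraction",
  "units": "fraction (display: %)",
  "n_factors": 5,
  "intercept": -3.97848306,
  "coefficients": {
    "X1": 0.31068222407,
    "X4": 0.6327387394,
    "X5": 0.006103641490,
    "X1*X1": -0.005977938516,
    "X2*X2": 0.0021886562363,
    "X4*X4": -0.022509013327,
    "X5*X5": -0.000031536339359,
    "X1*X3": -0.0019135332295,
    "X1*X4": -0.020236820212,
    "X1*X5": 0.00015411255817,
    "X3*X4": -0.0027135967924,
    "X3*X5": 0.00030307344603,
    "X4*X5": -0.00006432940808
  }
}
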