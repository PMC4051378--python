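{
  "response_name": "Y2",
  "response_scale": "raw",
  "units": "g/100 mL",
  "n_factors": 5,
  "intercept": -0.543313758,
  "coefficients": {
    "X1": 0.022952473674,
    "X3": 0.05158971648,
    "X4": 0.08619420430,
    "X5": -0.0013331394535,
    "X1*X1": -0.0004410784967,
    "X3*X3": -0.0013657027343,
    "X4*X4": -0.004819912252,
    "X1*X3": -0.0016301914750,
    "X1*X4": 0.00030259683893,
    "X1*X5": 0.000030318409839,
    "X3*X4": -0.004189833135,
    "X3*X5": 0.00020227979933,
    "X4*X5": 0.000021989005098
  }
}
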