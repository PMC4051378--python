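[
  {"name": "X1", "label": "starch", "minimum": 8.0, "maximum": 22.0, "n_levels": 15, "units": "g/L"},
  {"name": "X2", "label": "NaNO3", "minimum": 0.3, "maximum": 1.7, "n_levels": 15, "units": "g/L"},
  {"name": "X3", "label": "inoculum size", "minimum": 3.5, "maximum": 10.5, "n_levels": 15, "units": "% v/v"},
  {"name": "X4", "label": "initial pH", "minimum": 3.5, "maximum": 10.5, "n_levels": 15, "units": "pH"},
  {"name": "X5", "label": "fermentation time", "minimum": 60.0, "maximum": 228.0, "n_levels": 15, "units": "h"}
]
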