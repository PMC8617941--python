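{
  "label": "Porcine muscle, first-order temperature laws, 20–45 °C, 0.5–40 GHz",
  "temp_range_C": [20.0, 45.0],
  "laws": {
    "eps_inf": {"order": 1, "coefficients": [3.7529, -0.0746]},
    "sigma_s": {"order": 1, "coefficients": [0.9585, 0.0393]},
    "delta_eps": {"order": 1, "coefficients": [59.7534, -0.1545]},
    "tau": {"order": 1, "coefficients": [11.7765, -0.1243]},
    "alpha": {"order": 1, "coefficients": [0.1646, -0.0014]}
  }
}
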