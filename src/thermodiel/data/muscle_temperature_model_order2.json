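{
  "label": "Porcine muscle, second-order temperature laws, 20–45 °C, 0.5–40 GHz",
  "temp_range_C": [20.0, 45.0],
  "laws": {
    "eps_inf": {"order": 2, "coefficients": [5.9668, -0.2172, 0.0022]},
    "sigma_s": {"order": 2, "coefficients": [1.5166, 0.0033, 0.0005]},
    "delta_eps": {"order": 2, "coefficients": [67.3747, -0.6453, 0.0075]},
    "tau": {"order": 2, "coefficients": [14.3239, -0.2883, 0.0025]},
    "alpha": {"order": 2, "coefficients": [0.1159, 0.0018, -4.77e-05]}
  }
}
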