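{
  "Gabriel": {
    "label": "Gabriel",
    "citation": "S. Gabriel et al. (1996), parametric muscle model at 37 °C, γ + δ poles in the 0.5–40 GHz window",
    "eps_inf": 4.00,
    "sigma_s": 0.20,
    "poles": [
      {"delta_eps": 50.00, "tau_s": 7.23e-12, "alpha": 0.10},
      {"delta_eps": 7000, "tau_s": 353.68e-9, "alpha": 0.10}
    ]
  },
  "Peyman": {
    "label": "Peyman",
    "citation": "A. Peyman et al., muscle at 37 °C, 0.13–10 GHz, single pole",
    "eps_inf": 3.00,
    "sigma_s": 0.11,
    "poles": [
      {"delta_eps": 46.64, "tau_s": 12.21e-12, "alpha": 0.10}
    ]
  },
  "Abdilla": {
    "label": "Abdilla",
    "citation": "L. Abdilla et al., muscle at 37 °C, 0.5–40 GHz, single pole",
    "eps_inf": 11.78,
    "sigma_s": 0.95,
    "poles": [
      {"delta_eps": 39.45, "tau_s": 9.17e-12, "alpha": 0.10}
    ]
  },
  "Ley": {
    "label": "Ley",
    "citation": "S. Ley et al., muscle, temperature-dependent 30–50 °C model evaluated at 37 °C, two poles",
    "eps_inf": 4.75,
    "sigma_s": 0.53,
    "poles": [
      {"delta_eps": 50.73, "tau_s": 6.62e-12, "alpha": 0.18},
      {"delta_eps": 7000, "tau_s": 311.03e-9, "alpha": 0.18}
    ]
  },
  "This work (37 °C)": {
    "label": "This work (37 °C)",
    "citation": "Porcine muscle, single-pole fit at 37 °C from the 20–45 °C campaign",
    "eps_inf": 1.23,
    "sigma_s": 2.41,
    "poles": [
      {"delta_eps": 53.73, "tau_s": 7.21e-12, "alpha": 0.11}
    ]
  }
}
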