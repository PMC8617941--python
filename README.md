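# thermodiel

Temperature-dependent Cole–Cole dielectric modelling of muscle tissue over
0.5–40 GHz and 20–45 °C.

Designers of electromagnetic applicators — microwave ablation and
hyperthermia systems, implanted antennas, imaging arrays — need the complex
relative permittivity of tissue at the *operating* temperature, not just at
37 °C. For high-water-content tissue such as muscle the permittivity shifts
by roughly 2 % per °C, and ultra-wideband data above body temperature is
scarce. This package implements, as a reusable library, the modelling
chain behind a controlled open-ended-coaxial-probe study of porcine muscle:

* **Forward model** — multi-pole Cole–Cole permittivity

  ε(f) = ε∞ + Σₙ Δεₙ / (1 + (j2πf τₙ)^(1−αₙ)) + σs / (j2πf ε₀),

  with ε = ε′ − jε″, plus a packaged registry of literature muscle models
  at 37 °C (Gabriel, Peyman, Abdilla, Ley) and the published
  temperature-dependent model in which each of the five single-pole
  parameters (ε∞, σs, Δε, τ, α) follows a polynomial in tissue
  temperature.
* **Fitting** — per-sweep bounded least-squares estimation of the five
  Cole–Cole parameters from complex permittivity data (real and imaginary
  parts fitted simultaneously), then polynomial temperature laws with R²
  diagnostics and a pooled campaign RMSE.
* **Uncertainty** — random / systematic / drift decomposition of pre- and
  post-run reference-liquid validation sweeps into a combined complex
  uncertainty s_comb, and the ±1·s_comb error-bar non-overlap significance
  test.
* **Synthetic campaigns** — a generator reproducing the study design
  (8 set temperatures × 3 samples × 3 sites = 72 sweeps, 0.5–40 GHz in
  25 MHz steps) with temperature jitter, additive noise, contact-pressure
  sensitivity, dehydration logging, and optional δ-dispersion
  contamination, so the whole pipeline is testable end to end without any
  measurement data.
* **CLI** — `thermodiel simulate | fit | evaluate | compare | uncertainty
  | recover`.

## Worked example

```python
import thermodiel as td

model = td.published_temperature_model(order=1)

# body-temperature parameters from the packaged first-order laws
m37 = td.model_at_temperature(model, 37.0)
print(m37.sigma_s)           # 2.4126  S/m
print(m37.poles[0].alpha)    # 0.1128

# permittivity at the ISM bands
for f in (2.45e9, 5.8e9, 24.125e9):
    eps = m37.evaluate(f)
    print(f / 1e9, eps.real, -eps.imag)
#  2.450 GHz  eps' = 52.76   eps'' = 24.74
#  5.800 GHz  eps' = 48.44   eps'' = 20.97
# 24.125 GHz  eps' = 26.30   eps'' = 24.35

# where the 20 °C and 45 °C eps' curves cross (cold tissue is more
# polarizable below this frequency, less above it)
f_x = td.crossover_frequency(model, 20.0, 45.0, 0.5e9, 40e9)
print(f_x / 1e9)             # 6.53 GHz

# full pipeline on a synthetic campaign: simulate 72 noisy sweeps,
# refit every sweep, refit the temperature laws, score against truth
report = td.end_to_end_recovery(
    model, td.CampaignDesign(seed=1), td.ConfounderConfig(), order=1
)
print(report.rmse_fitted)                          # 0.502  (noise sd was 0.5)
print(report.median_relative_bias["delta_eps"])    # +0.0013
print(report.median_relative_bias["tau"])          # +0.0003
```

The campaign RMSE lands on the injected noise scale and the median
parameter biases are a few tenths of a percent — the inference chain is
essentially unbiased under the study's noise model.

The same flow from the shell:

```
thermodiel simulate --out camp --seed 1
thermodiel fit camp --order 1 --out fitdir
thermodiel evaluate --model fitdir/model.json --temperatures 37,43 --out eval.csv
thermodiel uncertainty camp --out scomb.csv
```

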