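# Methods

## Model

The package works with the multi-pole Cole–Cole description of the complex
relative permittivity of biological tissue,

    eps(f) = eps_inf + Σ_n Δeps_n / (1 + (j 2π f τ_n)^(1−α_n)) + σ_s / (j 2π f eps_0),

with the engineering convention `eps = eps' − j eps''`, so both parts are
non-negative for a passive material and the static-conductivity term
contributes `σ_s / (2π f eps_0)` to the loss part. `eps_0` is fixed at the
CODATA value 8.8541878128e-12 F/m so printed-precision checks are
reproducible. Frequencies are Hz and relaxation times seconds everywhere
inside the package; the picosecond/nanosecond conventions of printed
parameter tables are converted at the boundary (tau *temperature laws* are
the one deliberate exception — they are fitted and stored in picoseconds,
as such coefficient tables are printed, and converted to seconds when a
model is instantiated).

In the 0.5–40 GHz measurement band the γ dispersion (free tissue water)
dominates. The temperature-dependent model is a single γ-like pole whose
five parameters (eps_inf, σ_s, Δeps, τ, α) each follow a first- or
second-order polynomial in tissue temperature over 20–45 °C. The packaged
first-order coefficient set gives, e.g., σ_s(37 °C) = 2.41 S/m and
α(37 °C) = 0.11, and its 20 °C / 45 °C real-permittivity curves cross near
6.5 GHz — the point-like counterpart of the broader crossover zone
(roughly 6.5–10 GHz) seen in measured high-water-content tissue. Note the
low-frequency edge of this single-pole model deliberately omits the slow
δ dispersion (bound water, Δeps ≈ 7000 at τ ≈ 354 ns, relaxation frequency
0.45 MHz): within the measured band the δ tail contributes only ~10
permittivity units, far too little information to identify three more
parameters stably.

The `eps_inf ≥ 0` bound is intentionally not `≥ 1`: the published
first-order law evaluates to eps_inf(45 °C) ≈ 0.40, so a physical bound of
1 would reject the model itself; eps_inf here is an effective fit
parameter, not a vacuum limit.

A registry of literature muscle models at 37 °C (two-pole Gabriel and Ley,
single-pole Peyman, Abdilla, and the packaged campaign model) ships as JSON
with all relaxation times converted to seconds. The 37 °C registry row of
the campaign model is kept verbatim as printed; its eps_inf, Δeps and τ
differ in the third digit from the first-order laws evaluated at 37 °C
(1.23 vs 0.99, 53.73 vs 54.04, 7.21 vs 7.18 ps), so only σ_s and α — which
agree exactly — are used as cross-consistency anchors between the two
artifacts.

## Fitting

Stage 1 fits the five single-pole parameters per sweep by bounded
trust-region least squares (`scipy.optimize.least_squares`, `method="trf"`)
on the stacked residual `[eps'_model − eps'_data, eps''_model −
eps''_data]` — real and imaginary parts with equal unit weight, no
frequency weighting. Bounds are generous envelopes around all literature
values (eps_inf ∈ [0, 20], σ_s ∈ [0, 10] S/m, Δeps ∈ [0, 200],
τ ∈ [0.1, 100] ps, α ∈ [0, 0.5]); the default start is the literature
γ-pole (4, 0.2 S/m, 50, 7.23 ps, 0.1), reproducible and well inside the
bounds. τ is optimized in picoseconds with explicit column scaling so the
Jacobian is well conditioned on GHz grids. Tolerances: cost and step
1e-10, at most 5000 evaluations. Fits are deterministic; non-convergence
is flagged on the result rather than raised. When the optimizer parks
Δeps or τ on a zero lower bound (degenerate, dispersionless data) the
returned pole is floored at 1e-12 so the model type's strict positivity
invariants still hold.

Stage 2 regresses each per-sweep parameter on the *actual* (recorded)
sample temperature — not the set temperature — with an ordinary
least-squares polynomial of order 1 or 2, reporting R² = 1 − SS_res/SS_tot
per parameter. The default uses every sweep as a point (per-sweep scatter
is information about measurement spread); a `per_temperature_mean` switch
first averages within each set temperature. Order-2 never has lower R²
than order-1 on the same points (nested least squares), which the tests
assert as an invariant. Fitted laws take the data's temperature span as
their validity range and skip the construction-time physicality check:
under δ-tail contamination the fitted eps_inf law can dip marginally below
zero at the hot edge, and `model_at_temperature` clamps evaluated
parameters back into the physical region instead of refusing to evaluate.

Campaign goodness of fit is a pooled RMSE: real- and imaginary-part
residuals over all frequencies of all sweeps enter one root mean square
with equal weight.

A two-pole (γ + δ) fit exists for misspecification studies only; the band
carries almost no information about the δ pole, so it is deliberately not
part of the default pipeline.

## Uncertainty budget

From pre/post validation sweeps on a reference liquid, three per-frequency
components are computed separately for eps' and eps'':

* random — sample standard deviation pooled *within* the pre and post
  groups. Pooling across the groups instead would book any calibration
  drift between them as random scatter; with a single sweep per group the
  within-group dof is zero and the component is reported as 0.
* systematic — |mean of all sweeps − reference-model prediction|. The
  reference permittivity model is a required input (the synthetic
  generator supplies a known one, so no saline literature model is
  needed).
* drift — |mean(post) − mean(pre)|, reported as a magnitude.

They combine in quadrature into `s_comb`, and ±1·s_comb error bars feed
the significance rule: two measurements differ at a frequency when their
intervals do not overlap, `|m1 − m2| > s1 + s2`, with exactly touching
bars counted as not significant.

## Synthetic campaigns

The generator emulates the study design: 8 set temperatures (20, 25, 30,
35, 37, 40, 43, 45 °C) × 3 samples × 3 probing sites = 72 sweeps on the
0.5–40 GHz grid in 25 MHz steps (1581 points), bit-reproducible from one
seed. Per sweep it draws an actual temperature ~ N(set, 0.5 °C) (transport
from the water bath cools the sample; the 0.5 °C spread is a configuration
default, not a measured value), evaluates the truth model there, applies a
multiplicative contact-pressure effect of −0.3 %/kPa about the 15 kPa set
point with pressure ~ N(14.6, 0.61) kPa, and adds independent Gaussian
noise to each part (default sd 0.5 on both, the order of magnitude of a
combined measurement uncertainty; every test states its own value).
Optional δ-tail contamination adds the literature δ pole to the truth so
the single-pole fitting stage is genuinely misspecified — the fitted γ
parameters then skew exactly as expected (lower eps_inf; higher Δeps, α,
σ_s). Room humidity (71.4 ± 0.9 %) and room temperature (20.6 ± 0.4 °C)
are logged per sweep; dehydration draws a per-sample relative weight loss
(uniform up to 1 % at ≤ 40 °C, up to 6 % above) and affects the recorded
weights only — no permittivity consequence by default, since weight loss
is a monitoring guideline, not a calibrated permittivity law.

What the generator does **not** emulate: spatial heterogeneity of real
muscle, probe–sample contact artefacts, correlated (non-white) VNA noise,
calibration error beyond a constant validation drift offset, and any
dispersion physics below 0.5 GHz beyond the optional δ pole. Passing
recovery tests therefore demonstrate correctness of the inference
machinery under the stated statistical model, not instrument-level
fidelity.

The end-to-end harness (generate → fit per sweep → fit temperature laws →
pooled RMSE) reports truth-vs-estimate coefficient errors and per-sweep
median relative parameter bias. Noise-free and confounder-free, the whole
pipeline returns the generating first-order coefficients to better than
1e-6 relative; with 0.5-sd noise on the full 72-sweep design the median
Δeps and τ biases stay well below 1 %.

## Numerical choices

* Crossover finding scans 4096 log-spaced points for sign changes of
  eps'(f, T1) − eps'(f, T2), then bisects a unique bracket to 1e-9
  relative tolerance; no sign change returns `None`, several raise an
  ambiguity error listing the brackets. An everywhere-zero difference
  (identical curves) is "no crossover". Sign changes closer than the scan
  resolution would be missed; at 4096 points over the band that is ~2 ‰
  in frequency.
* All pairwise crossovers of the packaged first-order model land between
  6.10 and 7.12 GHz — a ~1 GHz cluster around 6.5 GHz rather than a
  single point, mirroring the broadened crossover zone of real
  measurements.
* Campaign CSVs store frequencies as integers when the grid is integral
  in Hz, and reading uses round-trip float parsing, so write→read is
  bit-exact.
* The degenerate constant sweep (Δeps → 0) is accepted and returns the
  increment at its lower bound with near-zero cost; single-frequency or
  sub-decade sweeps are rejected up front.

## Test-design notes

Monte-Carlo recovery of the random uncertainty component is checked on the
aggregate (median over the frequency grid): a sample standard deviation
from 20 sweeps scatters ~16 % (relative) per frequency, so no per-frequency
band tighter than that can hold uniformly. Heavier stochastic checks run
at the study's own scale (72 sweeps × 1581 points, 5 seeds), which the
optimizer handles in well under a minute per campaign.
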