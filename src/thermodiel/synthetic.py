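"""Synthetic measurement campaigns with the statistical structure of a
controlled dielectric-probe study on muscle tissue.

The default design mirrors the study layout: 8 set temperatures (20, 25,
30, 35, 37, 40, 43, 45 °C), 3 samples x 3 probing sites each (72 sweeps),
on a 0.5–40 GHz grid with 25 MHz steps (1581 points).  Each sweep draws an
*actual* temperature around its set point (transport from the water bath to
the probe cools the sample), evaluates a truth model there, then applies
the named confounders:

* an optional delta-dispersion tail pole, emulating the slow bound-water
  relaxation that a single-pole gamma fit deliberately omits;
* a multiplicative probe contact-pressure effect, −0.3 %/kPa around the
  15 kPa set point, with per-sweep pressure drawn around 14.6 ± 0.61 kPa;
* additive Gaussian noise on eps' and eps'' at the combined-uncertainty
  scale;
* dehydration recorded as per-sample weight loss (below 1 % up to 40 °C,
  up to 6 % above), affecting the logged weights only.

Room humidity (71.4 ± 0.9 %) and room temperature (20.6 ± 0.4 °C) are
logged per sweep.  Campaigns are bit-reproducible from the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .campaign import FrequencySweep, MeasurementCampaign
from .models import (
    ColeColeModel,
    ColeColePole,
    TemperatureColeColeModel,
)
from .uncertainty import ValidationPair

__all__ = [
    "GABRIEL_DELTA_TAIL",
    "CampaignDesign",
    "ConfounderConfig",
    "FrequencySweep",
    "MeasurementCampaign",
    "RecoveryReport",
    "generate_campaign",
    "generate_validation_sweeps",
    "end_to_end_recovery",
]

#: Literature delta-dispersion pole for muscle (increment 7000, 353.68 ns,
#: broadening 0.10): the canonical tail added by ``ConfounderConfig.delta_tail``.
GABRIEL_DELTA_TAIL = ColeColePole(delta_eps=7000.0, tau=353.68e-9, alpha=0.10)

#: Contact-pressure set point of the lifting platform, kPa.
PRESSURE_SETPOINT_KPA = 15.0


@dataclass(frozen=True)
class CampaignDesign:
    """Study layout: set temperatures, replication and frequency grid."""

    set_temperatures: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 37.0, 40.0, 43.0, 45.0)
    samples_per_temperature: int = 3
    sites_per_sample: int = 3
    f_start: float = 0.5e9
    f_stop: float = 40.0e9
    f_step: float = 25.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.set_temperatures:
            raise ValueError("need at least one set temperature")
        if self.samples_per_temperature < 1 or self.sites_per_sample < 1:
            raise ValueError("replication counts must be >= 1")
        if not 0 < self.f_start < self.f_stop or self.f_step <= 0:
            raise ValueError("invalid frequency grid specification")

    @property
    def frequency_grid(self) -> np.ndarray:
        """Hz grid, inclusive of both endpoints when the step divides the span."""
        return np.arange(self.f_start, self.f_stop + self.f_step / 2, self.f_step)

    @property
    def n_sweeps(self) -> int:
        return len(self.set_temperatures) * self.samples_per_temperature * self.sites_per_sample


@dataclass(frozen=True)
class ConfounderConfig:
    """Noise and confounder settings; all spreads are standard deviations.

    ``delta_tail`` is off (None) by default; pass :data:`GABRIEL_DELTA_TAIL`
    to contaminate the truth with the literature delta pole.
    ``pressure_sensitivity`` is the relative permittivity change per kPa of
    contact pressure away from the 15 kPa set point, applied
    multiplicatively to both parts.
    """

    temp_jitter_sd: float = 0.5
    noise_sd_re: float = 0.5
    noise_sd_im: float = 0.5
    delta_tail: Optional[ColeColePole] = None
    pressure_mean_kPa: float = 14.6
    pressure_sd_kPa: float = 0.61
    pressure_sensitivity: float = -0.003
    humidity_mean: float = 71.4
    humidity_sd: float = 0.9
    room_temp_mean: float = 20.6
    room_temp_sd: float = 0.4
    weight_loss_max_below_40C: float = 0.01
    weight_loss_max_above_40C: float = 0.06
    sample_weight_mean_g: float = 8.5
    sample_weight_sd_g: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "temp_jitter_sd", "noise_sd_re", "noise_sd_im",
            "pressure_sd_kPa", "humidity_sd", "room_temp_sd", "sample_weight_sd_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "ConfounderConfig":
        """All randomness and confounders switched off: sweeps reproduce the
        truth model at the set temperatures exactly."""
        return cls(
            temp_jitter_sd=0.0,
            noise_sd_re=0.0,
            noise_sd_im=0.0,
            delta_tail=None,
            pressure_mean_kPa=PRESSURE_SETPOINT_KPA,
            pressure_sd_kPa=0.0,
            humidity_sd=0.0,
            room_temp_sd=0.0,
            weight_loss_max_below_40C=0.0,
            weight_loss_max_above_40C=0.0,
            sample_weight_sd_g=0.0,
        )


def generate_campaign(
    truth: TemperatureColeColeModel,
    design: CampaignDesign | None = None,
    confounders: ConfounderConfig | None = None,
) -> MeasurementCampaign:
    """Simulate a measurement campaign from a truth temperature model.

    Per sweep, in a fixed draw order (so campaigns are bit-reproducible
    from ``design.seed``): actual temperature ~ N(set, jitter), contact
    pressure ~ N(mean, sd), additive Gaussian noise on each part, room
    humidity and temperature for the environment log.  Per sample one
    weight and one dehydration fraction are drawn.
    """
    design = design or CampaignDesign()
    cfg = confounders or ConfounderConfig()
    rng = np.random.default_rng(design.seed)
    grid = design.frequency_grid
    n = grid.size

    sweeps: list[FrequencySweep] = []
    env_rows: list[dict] = []
    for set_T in design.set_temperatures:
        for sample in range(1, design.samples_per_temperature + 1):
            weight_before = rng.normal(cfg.sample_weight_mean_g, cfg.sample_weight_sd_g)
            loss_max = (
                cfg.weight_loss_max_below_40C
                if set_T <= 40.0
                else cfg.weight_loss_max_above_40C
            )
            loss_frac = rng.uniform(0.0, loss_max) if loss_max > 0 else 0.0
            weight_after = weight_before * (1.0 - loss_frac)
            for site in range(1, design.sites_per_sample + 1):
                actual_T = rng.normal(set_T, cfg.temp_jitter_sd)
                model = truth.at_temperature(actual_T, mode="ignore")
                if cfg.delta_tail is not None:
                    model = model.with_pole(cfg.delta_tail)
                eps = model.evaluate(grid)
                pressure = rng.normal(cfg.pressure_mean_kPa, cfg.pressure_sd_kPa)
                factor = 1.0 + cfg.pressure_sensitivity * (pressure - PRESSURE_SETPOINT_KPA)
                eps_re = eps.real * factor + rng.normal(0.0, cfg.noise_sd_re, n)
                eps_im = -eps.imag * factor + rng.normal(0.0, cfg.noise_sd_im, n)
                humidity = rng.normal(cfg.humidity_mean, cfg.humidity_sd)
                room_T = rng.normal(cfg.room_temp_mean, cfg.room_temp_sd)
                sweeps.append(
                    FrequencySweep(
                        frequencies=grid.copy(),
                        eps_real=eps_re,
                        eps_imag=eps_im,
                        actual_temperature=float(actual_T),
                        set_temperature=float(set_T),
                        sample_id=sample,
                        site_id=site,
                        contact_pressure_kPa=float(pressure),
                        weight_before_g=float(weight_before),
                        weight_after_g=float(weight_after),
                    )
                )
                env_rows.append(
                    {
                        "sweep": len(sweeps) - 1,
                        "set_temperature_C": set_T,
                        "humidity_pct": float(humidity),
                        "room_temperature_C": float(room_T),
                    }
                )
    return MeasurementCampaign(
        sweeps=sweeps,
        environment_log=pd.DataFrame(env_rows),
        truth=truth,
    )


def generate_validation_sweeps(
    reference: ColeColeModel,
    n_pre: int = 3,
    n_post: int = 3,
    noise_sd: float = 0.1,
    drift_offset_re: float = 0.0,
    drift_offset_im: float = 0.0,
    frequencies: np.ndarray | None = None,
    liquid_temperature_C: float = 20.6,
    seed: int = 0,
) -> ValidationPair:
    """Simulate pre/post reference-liquid validation sweeps.

    Pre sweeps are the reference model plus i.i.d. Gaussian noise on each
    part; post sweeps additionally carry a constant drift offset on eps'
    (and optionally eps''), emulating calibration ageing over the run.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("need at least one pre and one post sweep")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if frequencies is None:
        frequencies = CampaignDesign().frequency_grid
    frequencies = np.asarray(frequencies, dtype=float)
    rng = np.random.default_rng(seed)
    eps = reference.evaluate(frequencies)
    base_re, base_im = eps.real, -eps.imag
    n = frequencies.size

    def make(offset_re: float, offset_im: float) -> FrequencySweep:
        return FrequencySweep(
            frequencies=frequencies.copy(),
            eps_real=base_re + offset_re + rng.normal(0.0, noise_sd, n),
            eps_imag=base_im + offset_im + rng.normal(0.0, noise_sd, n),
            actual_temperature=liquid_temperature_C,
        )

    pre = [make(0.0, 0.0) for _ in range(n_pre)]
    post = [make(drift_offset_re, drift_offset_im) for _ in range(n_post)]
    return ValidationPair(pre_sweeps=pre, post_sweeps=post, reference=reference)


# ---------------------------------------------------------------------------
# End-to-end recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Truth-vs-refit comparison for a simulated campaign.

    ``median_relative_bias`` holds, per parameter, the median over sweeps
    of the signed relative error of the per-sweep fit against the truth
    value at that sweep's actual temperature.  ``coefficient_relative_error``
    compares refitted polynomial coefficients with the truth coefficients
    (only populated when the truth laws have the requested order).
    """

    campaign: MeasurementCampaign
    fitted: TemperatureColeColeModel
    fits: list  # list[FitResult]
    polynomial_fits: dict
    median_relative_bias: dict[str, float]
    coefficient_relative_error: dict[str, np.ndarray]
    rmse_fitted: float
    rmse_truth: float

    def parameter_table(self) -> pd.DataFrame:
        """Per-sweep fitted parameters vs actual temperature."""
        from .fitting import fit_results_table

        return fit_results_table(self.fits)


def end_to_end_recovery(
    truth: TemperatureColeColeModel,
    design: CampaignDesign | None = None,
    confounders: ConfounderConfig | None = None,
    order: int = 1,
) -> RecoveryReport:
    """Run the full pipeline on a synthetic campaign and score it.

    generate -> per-sweep single-pole fit -> polynomial temperature laws ->
    pooled campaign RMSE, reporting truth-vs-estimate discrepancies.
    """
    from .fitting import fit_parameter_polynomials, fit_single_pole, model_rmse

    campaign = generate_campaign(truth, design, confounders)
    fits = [fit_single_pole(sweep) for sweep in campaign.sweeps]
    fitted, polyfits = fit_parameter_polynomials(fits, order=order)

    # per-sweep signed relative bias vs truth at the sweep's actual temperature
    bias: dict[str, list[float]] = {name: [] for name in
                                    ("eps_inf", "sigma_s", "delta_eps", "tau", "alpha")}
    for fit in fits:
        true_model = truth.at_temperature(fit.actual_temperature, mode="ignore")
        est_model = fit.model
        truth_vals = {
            "eps_inf": true_model.eps_inf,
            "sigma_s": true_model.sigma_s,
            "delta_eps": true_model.poles[0].delta_eps,
            "tau": true_model.poles[0].tau,
            "alpha": true_model.poles[0].alpha,
        }
        est_vals = {
            "eps_inf": est_model.eps_inf,
            "sigma_s": est_model.sigma_s,
            "delta_eps": est_model.poles[0].delta_eps,
            "tau": est_model.poles[0].tau,
            "alpha": est_model.poles[0].alpha,
        }
        for name, tv in truth_vals.items():
            denom = tv if tv != 0 else 1.0
            bias[name].append((est_vals[name] - tv) / denom)
    median_bias = {name: float(np.median(vals)) for name, vals in bias.items()}

    coeff_err: dict[str, np.ndarray] = {}
    for law in fitted.laws:
        true_law = truth.law(law.name)
        if true_law.order == law.order:
            t = np.asarray(true_law.coefficients, dtype=float)
            e = np.asarray(law.coefficients, dtype=float)
            denom = np.where(t != 0, np.abs(t), 1.0)
            coeff_err[law.name] = np.abs(e - t) / denom

    return RecoveryReport(
        campaign=campaign,
        fitted=fitted,
        fits=fits,
        polynomial_fits=polyfits,
        median_relative_bias=median_bias,
        coefficient_relative_error=coeff_err,
        rmse_fitted=model_rmse(fitted, campaign, mode="ignore"),
        rmse_truth=model_rmse(truth, campaign, mode="ignore"),
    )
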