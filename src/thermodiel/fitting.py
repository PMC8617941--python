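"""Two-stage inference for temperature-dependent Cole–Cole models.

Stage 1 fits a single-pole Cole–Cole model (eps_inf, sigma_s, delta_eps,
tau, alpha) to each measured sweep by bounded trust-region least squares on
the stacked real/imaginary residual — real and imaginary parts enter with
equal unit weight and no frequency weighting.  Stage 2 regresses each of
the five per-sweep parameters on the *actual* sample temperature with an
ordinary first- or second-order polynomial, yielding a
:class:`~thermodiel.models.TemperatureColeColeModel` plus per-parameter R².

The optimizer works on a conditioned parameter vector (tau in picoseconds,
explicit column scaling) so the Jacobian is well-behaved on GHz grids;
results are reported in SI units.  Fits are deterministic: the same sweep,
start and bounds always give bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .campaign import FrequencySweep, MeasurementCampaign
from .models import (
    EPS0,
    ColeColeModel,
    ColeColePole,
    TemperatureColeColeModel,
    TemperatureParameterLaw,
    model_at_temperature,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
    "FitResult",
    "PolynomialFitResult",
    "fit_single_pole",
    "fit_two_pole",
    "fit_parameter_polynomials",
    "fit_results_table",
    "model_rmse",
    "compare_models",
]

#: Default parameter bounds (tau in picoseconds): generous envelopes around
#: all literature muscle values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "eps_inf": (0.0, 20.0),
    "sigma_s": (0.0, 10.0),
    "delta_eps": (0.0, 200.0),
    "tau": (0.1, 100.0),  # ps
    "alpha": (0.0, 0.5),
}

#: Default starting point: the literature gamma-dispersion values for
#: muscle (a reproducible start well inside the bounds).
DEFAULT_INIT = ColeColeModel(
    eps_inf=4.0,
    sigma_s=0.2,
    poles=(ColeColePole(delta_eps=50.0, tau=7.23e-12, alpha=0.10),),
    label="default start (literature gamma pole)",
)

_X_SCALE = np.array([1.0, 1.0, 10.0, 10.0, 0.1])
_FTOL = 1e-10
_XTOL = 1e-10
_MAX_NFEV = 5000

# floor used when a fit pushes delta_eps or tau onto a zero lower bound,
# so the returned model still satisfies the strict pole invariants
_POLE_FLOOR = 1e-12


@dataclass
class FitResult:
    """Outcome of one per-sweep fit.

    ``residual_norm`` is the final cost, i.e. half the sum of squared
    stacked real/imaginary residuals."""

    model: ColeColeModel
    residual_norm: float
    n_iterations: int
    converged: bool
    actual_temperature: float
    set_temperature: Optional[float] = None
    covariance_proxy: Optional[np.ndarray] = None

    def parameters(self) -> dict[str, float]:
        pole = self.model.poles[0]
        return {
            "eps_inf": self.model.eps_inf,
            "sigma_s": self.model.sigma_s,
            "delta_eps": pole.delta_eps,
            "tau": pole.tau,
            "alpha": pole.alpha,
        }


@dataclass
class PolynomialFitResult:
    """One parameter's polynomial temperature law with its diagnostics."""

    law: TemperatureParameterLaw
    r_squared: float
    residuals: np.ndarray
    temperatures: np.ndarray
    values: np.ndarray


def _validate_sweep(sweep: FrequencySweep) -> None:
    f = sweep.frequencies
    if f.size < 10:
        raise ValueError(f"sweep has {f.size} points; need >= 10")
    if f[-1] / f[0] < 10.0:
        raise ValueError("sweep must span at least one frequency decade")
    if np.any(~np.isfinite(sweep.eps_real)) or np.any(~np.isfinite(sweep.eps_imag)):
        raise ValueError("sweep contains NaN/inf permittivity values")


def _unpack_bounds(bounds: Mapping[str, tuple[float, float]] | None) -> tuple[np.ndarray, np.ndarray]:
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        unknown = set(bounds) - set(DEFAULT_BOUNDS)
        if unknown:
            raise ValueError(f"unknown bound names: {sorted(unknown)}")
        merged.update(bounds)
    order = ("eps_inf", "sigma_s", "delta_eps", "tau", "alpha")
    lo = np.array([merged[k][0] for k in order])
    hi = np.array([merged[k][1] for k in order])
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy lo < hi")
    return lo, hi


def _single_pole_eps(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Model permittivity for parameter vector (eps_inf, sigma_s, delta_eps,
    tau_ps, alpha) at angular frequencies w."""
    eps_inf, sigma_s, delta_eps, tau_ps, alpha = x
    eps = eps_inf + delta_eps / (1.0 + (1j * w * tau_ps * 1e-12) ** (1.0 - alpha))
    return eps + sigma_s / (1j * w * EPS0)


def fit_single_pole(
    sweep: FrequencySweep,
    init: ColeColeModel | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Fit the five single-pole Cole–Cole parameters to one sweep.

    Minimizes the stacked residual ``[eps'_model - eps'_data,
    eps''_model - eps''_data]`` by bounded trust-region least squares.
    Non-convergence is flagged on the result, not raised.
    """
    _validate_sweep(sweep)
    lo, hi = _unpack_bounds(bounds)
    init = init or DEFAULT_INIT
    if len(init.poles) != 1:
        raise ValueError("init must be a single-pole model")
    x0 = np.array(
        [
            init.eps_inf,
            init.sigma_s,
            init.poles[0].delta_eps,
            init.poles[0].tau * 1e12,
            init.poles[0].alpha,
        ]
    )
    x0 = np.clip(x0, lo, hi)

    w = 2.0 * np.pi * sweep.frequencies
    data_re = sweep.eps_real
    data_im = sweep.eps_imag

    def residual(x: np.ndarray) -> np.ndarray:
        eps = _single_pole_eps(x, w)
        return np.concatenate([eps.real - data_re, -eps.imag - data_im])

    res = least_squares(
        residual,
        x0,
        bounds=(lo, hi),
        method="trf",
        x_scale=_X_SCALE,
        ftol=_FTOL,
        xtol=_XTOL,
        gtol=None,
        max_nfev=_MAX_NFEV,
    )

    eps_inf, sigma_s, delta_eps, tau_ps, alpha = res.x
    model = ColeColeModel(
        eps_inf=max(eps_inf, 0.0),
        sigma_s=max(sigma_s, 0.0),
        poles=(
            ColeColePole(
                delta_eps=max(delta_eps, _POLE_FLOOR),
                tau=max(tau_ps, _POLE_FLOOR) * 1e-12,
                alpha=min(max(alpha, 0.0), np.nextafter(1.0, 0.0)),
            ),
        ),
        label="single-pole fit",
    )
    cov = _covariance_proxy(res)
    return FitResult(
        model=model,
        residual_norm=float(res.cost),
        n_iterations=int(res.nfev),
        converged=bool(res.status > 0),
        actual_temperature=float(sweep.actual_temperature),
        set_temperature=sweep.set_temperature,
        covariance_proxy=cov,
    )


def _covariance_proxy(res) -> Optional[np.ndarray]:
    """Jacobian-based dispersion estimate sigma^2 (J^T J)^-1; None when the
    Jacobian is rank-deficient or the fit is exactly interpolating."""
    try:
        J = res.jac
        dof = J.shape[0] - J.shape[1]
        if dof <= 0:
            return None
        s2 = 2.0 * res.cost / dof
        return s2 * np.linalg.pinv(J.T @ J)
    except Exception:
        return None


def fit_two_pole(
    sweep: FrequencySweep,
    init_tail: ColeColePole | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Two-pole (gamma + delta) fit, for misspecification studies only.

    The measured 0.5–40 GHz band carries almost no information about a
    sub-GHz delta pole, so this fit is numerically ill-posed by design and
    is not part of the default pipeline.  The tail pole's increment and
    relaxation time (in ns) are appended to the single-pole parameter
    vector; its alpha is held at the init value.
    """
    _validate_sweep(sweep)
    lo5, hi5 = _unpack_bounds(bounds)
    tail = init_tail or ColeColePole(7000.0, 353.68e-9, 0.10)
    x0 = np.array(
        [
            DEFAULT_INIT.eps_inf,
            DEFAULT_INIT.sigma_s,
            DEFAULT_INIT.poles[0].delta_eps,
            DEFAULT_INIT.poles[0].tau * 1e12,
            DEFAULT_INIT.poles[0].alpha,
            tail.delta_eps,
            tail.tau * 1e9,
        ]
    )
    lo = np.concatenate([lo5, [0.0, 1.0]])
    hi = np.concatenate([hi5, [50000.0, 5000.0]])
    x0 = np.clip(x0, lo, hi)
    w = 2.0 * np.pi * sweep.frequencies
    alpha2 = tail.alpha

    def residual(x: np.ndarray) -> np.ndarray:
        eps = _single_pole_eps(x[:5], w)
        eps = eps + x[5] / (1.0 + (1j * w * x[6] * 1e-9) ** (1.0 - alpha2))
        return np.concatenate([eps.real - sweep.eps_real, -eps.imag - sweep.eps_imag])

    res = least_squares(
        residual,
        x0,
        bounds=(lo, hi),
        method="trf",
        x_scale=np.concatenate([_X_SCALE, [1000.0, 100.0]]),
        ftol=_FTOL,
        xtol=_XTOL,
        gtol=None,
        max_nfev=_MAX_NFEV,
    )
    eps_inf, sigma_s, d1, tau1_ps, a1, d2, tau2_ns = res.x
    model = ColeColeModel(
        eps_inf=max(eps_inf, 0.0),
        sigma_s=max(sigma_s, 0.0),
        poles=(
            ColeColePole(max(d1, _POLE_FLOOR), max(tau1_ps, _POLE_FLOOR) * 1e-12, a1),
            ColeColePole(max(d2, _POLE_FLOOR), max(tau2_ns, _POLE_FLOOR) * 1e-9, alpha2),
        ),
        label="two-pole fit (misspecification study)",
    )
    return FitResult(
        model=model,
        residual_norm=float(res.cost),
        n_iterations=int(res.nfev),
        converged=bool(res.status > 0),
        actual_temperature=float(sweep.actual_temperature),
        set_temperature=sweep.set_temperature,
        covariance_proxy=None,
    )


# ---------------------------------------------------------------------------
# Stage 2: polynomial temperature laws
# ---------------------------------------------------------------------------

def fit_parameter_polynomials(
    fits: Sequence[FitResult],
    order: int = 1,
    use: str = "per_sweep",
    label: str = "fitted temperature model",
) -> tuple[TemperatureColeColeModel, dict[str, PolynomialFitResult]]:
    """Regress each Cole–Cole parameter on actual temperature.

    ``use="per_sweep"`` fits through every individual sweep's parameters
    (the default); ``use="per_temperature_mean"`` first averages parameters
    and actual temperatures within each set temperature.  The tau law is
    fitted in picoseconds, matching the printed convention.  R² is
    ``1 - SS_res / SS_tot``.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if use not in ("per_sweep", "per_temperature_mean"):
        raise ValueError(f"unknown aggregation {use!r}")
    if not fits:
        raise ValueError("no fit results given")

    T = np.array([f.actual_temperature for f in fits], dtype=float)
    values = {
        name: np.array([f.parameters()[name] for f in fits], dtype=float)
        for name in ("eps_inf", "sigma_s", "delta_eps", "tau", "alpha")
    }
    values["tau"] = values["tau"] * 1e12  # fit the tau law in picoseconds

    if use == "per_temperature_mean":
        set_T = [f.set_temperature for f in fits]
        if any(t is None for t in set_T):
            raise ValueError("per_temperature_mean needs set_temperature on every fit")
        groups = sorted(set(set_T))
        idx = [np.array([i for i, t in enumerate(set_T) if t == g]) for g in groups]
        T = np.array([T[i].mean() for i in idx])
        values = {name: np.array([v[i].mean() for i in idx]) for name, v in values.items()}

    if np.unique(T).size < order + 2:
        raise ValueError(
            f"need at least {order + 2} distinct temperatures for an order-{order} fit, "
            f"got {np.unique(T).size}"
        )

    temp_range = (float(T.min()), float(T.max()))
    laws: list[TemperatureParameterLaw] = []
    diagnostics: dict[str, PolynomialFitResult] = {}
    for name, y in values.items():
        coeffs = np.polynomial.polynomial.polyfit(T, y, order)
        fitted = np.polynomial.polynomial.polyval(T, coeffs)
        resid = y - fitted
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot > 0:
            r2 = 1.0 - ss_res / ss_tot
        else:
            r2 = 1.0 if ss_res <= 1e-20 * max(1.0, float(np.sum(y**2))) else 0.0
        # data-driven laws may exit the physical region marginally at a
        # range edge (e.g. eps_inf under delta-tail contamination);
        # model_at_temperature clamps them back at evaluation
        law = TemperatureParameterLaw(
            name, order, tuple(coeffs), temp_range, validate_physical=False
        )
        laws.append(law)
        diagnostics[name] = PolynomialFitResult(
            law=law, r_squared=r2, residuals=resid, temperatures=T.copy(), values=y.copy()
        )
    tmodel = TemperatureColeColeModel(tuple(laws), label=label)
    return tmodel, diagnostics


def fit_results_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Per-sweep parameter table (tau reported in picoseconds)."""
    rows = []
    for f in fits:
        p = f.parameters()
        rows.append(
            {
                "actual_temperature_C": f.actual_temperature,
                "set_temperature_C": f.set_temperature,
                "eps_inf": p["eps_inf"],
                "sigma_s_S_per_m": p["sigma_s"],
                "delta_eps": p["delta_eps"],
                "tau_ps": p["tau"] * 1e12,
                "alpha": p["alpha"],
                "residual_norm": f.residual_norm,
                "n_iterations": f.n_iterations,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def model_rmse(
    tmodel: TemperatureColeColeModel,
    campaign: MeasurementCampaign,
    mode: str = "warn",
) -> float:
    """Pooled RMSE of a temperature model over a campaign.

    Real- and imaginary-part residuals across all frequencies of all
    sweeps are pooled with equal weight into one root mean square.
    ``mode`` controls out-of-range actual temperatures (see
    :func:`~thermodiel.models.model_at_temperature`).
    """
    if len(campaign) == 0:
        raise ValueError("empty campaign")
    total = 0.0
    count = 0
    for sweep in campaign.sweeps:
        eps = model_at_temperature(tmodel, sweep.actual_temperature, mode=mode).evaluate(
            sweep.frequencies
        )
        total += float(np.sum((eps.real - sweep.eps_real) ** 2))
        total += float(np.sum((-eps.imag - sweep.eps_imag) ** 2))
        count += 2 * sweep.frequencies.size
    return math.sqrt(total / count)


def compare_models(models: Sequence[ColeColeModel], frequencies) -> pd.DataFrame:
    """Side-by-side eps'/eps'' table for a list of models on one grid."""
    if not models:
        raise ValueError("no models given")
    frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if frequencies.size == 0:
        raise ValueError("empty frequency grid")
    out = {"frequency_Hz": frequencies}
    seen: dict[str, int] = {}
    for i, model in enumerate(models):
        label = model.label or f"model_{i}"
        if label in seen:
            seen[label] += 1
            label = f"{label}#{seen[label]}"
        else:
            seen[label] = 0
        eps = model.evaluate(frequencies)
        out[f"{label}:eps_real"] = np.atleast_1d(eps.real)
        out[f"{label}:eps_imag"] = np.atleast_1d(-eps.imag)
    return pd.DataFrame(out)
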