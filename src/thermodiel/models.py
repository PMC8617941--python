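"""Multi-pole Cole–Cole dielectric models and their temperature dependence.

The complex relative permittivity of a tissue with ``N`` relaxation
processes (poles) and a static ionic conductivity ``sigma_s`` is

    eps(f) = eps_inf + sum_n  delta_eps_n / (1 + (j 2 pi f tau_n)^(1 - alpha_n))
                     + sigma_s / (j 2 pi f eps_0)

with the engineering sign convention ``eps = eps' - j eps''`` so that both
the stored part ``eps'`` and the loss part ``eps''`` are non-negative for a
passive material.  The conductivity term contributes
``sigma_s / (2 pi f eps_0)`` to ``eps''``.

A single-pole model whose five parameters (eps_inf, sigma_s, delta_eps,
tau, alpha) each follow a low-order polynomial in tissue temperature gives
the temperature-dependent muscle model covering 20–45 °C and 0.5–40 GHz;
the published coefficient sets ship as packaged JSON and are loaded with
:func:`published_temperature_model` and :func:`literature_models`.

Units are SI throughout: frequency in Hz, relaxation time in seconds,
conductivity in S/m — except that the temperature *laws* for tau are
expressed in picoseconds, matching how such coefficient tables are printed;
:func:`model_at_temperature` converts back to seconds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "EPS0",
    "PARAMETER_NAMES",
    "AmbiguousCrossoverError",
    "ColeColePole",
    "ColeColeModel",
    "TemperatureParameterLaw",
    "TemperatureColeColeModel",
    "evaluate_permittivity",
    "model_at_temperature",
    "relaxation_frequency",
    "crossover_frequency",
    "literature_models",
    "published_temperature_model",
]

#: Vacuum permittivity, CODATA value, F/m.
EPS0 = 8.8541878128e-12

#: The five single-pole Cole–Cole parameters, in canonical order.
PARAMETER_NAMES = ("eps_inf", "sigma_s", "delta_eps", "tau", "alpha")


class AmbiguousCrossoverError(RuntimeError):
    """Raised when more than one sign change exists on a crossover bracket.

    The offending sub-brackets (Hz pairs) are available as ``.brackets``.
    """

    def __init__(self, brackets: list[tuple[float, float]]):
        self.brackets = brackets
        super().__init__(
            f"{len(brackets)} sign changes on bracket; sub-brackets (Hz): {brackets}"
        )


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ColeColePole:
    """One relaxation process: increment ``delta_eps``, time ``tau`` [s],
    broadening exponent ``alpha`` (0 recovers a Debye pole)."""

    delta_eps: float
    tau: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_eps", _check_finite("delta_eps", self.delta_eps))
        object.__setattr__(self, "tau", _check_finite("tau", self.tau))
        object.__setattr__(self, "alpha", _check_finite("alpha", self.alpha))
        if self.delta_eps <= 0:
            raise ValueError(f"delta_eps must be > 0, got {self.delta_eps}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ColeColeModel:
    """A multi-pole Cole–Cole model: ``eps_inf``, ``sigma_s`` [S/m] and an
    ordered list of poles (possibly empty)."""

    eps_inf: float
    sigma_s: float = 0.0
    poles: tuple[ColeColePole, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "eps_inf", _check_finite("eps_inf", self.eps_inf))
        object.__setattr__(self, "sigma_s", _check_finite("sigma_s", self.sigma_s))
        object.__setattr__(self, "poles", tuple(self.poles))
        if self.eps_inf < 0:
            raise ValueError(f"eps_inf must be >= 0, got {self.eps_inf}")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")

    def evaluate(self, frequencies) -> np.ndarray:
        """Complex relative permittivity (``eps' - j eps''``) on a Hz grid."""
        return evaluate_permittivity(self, frequencies)

    def with_pole(self, pole: ColeColePole) -> "ColeColeModel":
        """A copy of this model with one extra pole appended."""
        return ColeColeModel(self.eps_inf, self.sigma_s, self.poles + (pole,), self.label)

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "eps_inf": self.eps_inf,
            "sigma_s": self.sigma_s,
            "poles": [
                {"delta_eps": p.delta_eps, "tau_s": p.tau, "alpha": p.alpha}
                for p in self.poles
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColeColeModel":
        poles = tuple(
            ColeColePole(p["delta_eps"], p["tau_s"], p["alpha"]) for p in d.get("poles", [])
        )
        return cls(d["eps_inf"], d.get("sigma_s", 0.0), poles, d.get("label", ""))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "ColeColeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def evaluate_permittivity(model: ColeColeModel, frequencies) -> np.ndarray:
    """Evaluate a Cole–Cole model on a positive frequency grid.

    Parameters
    ----------
    model : ColeColeModel
    frequencies : array_like
        Frequencies in Hz, all strictly positive.

    Returns
    -------
    numpy.ndarray of complex
        ``eps' - j eps''`` per frequency; ``eps'' = -imag`` is non-negative
        for any model satisfying the field invariants.
    """
    f = np.asarray(frequencies, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if f.size == 0:
        return f.astype(complex)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("frequencies must be finite and strictly positive (Hz)")
    w = 2.0 * np.pi * f
    eps = np.full(f.shape, model.eps_inf, dtype=complex)
    for pole in model.poles:
        eps += pole.delta_eps / (1.0 + (1j * w * pole.tau) ** (1.0 - pole.alpha))
    if model.sigma_s != 0.0:
        eps += model.sigma_s / (1j * w * EPS0)
    return eps[0] if scalar else eps


def relaxation_frequency(pole: ColeColePole | float) -> float:
    """Relaxation frequency ``(2 pi tau)^-1`` in Hz of a pole (or a bare tau
    in seconds)."""
    tau = pole.tau if isinstance(pole, ColeColePole) else float(pole)
    if not math.isfinite(tau) or tau <= 0:
        raise ValueError(f"tau must be positive and finite, got {tau}")
    return 1.0 / (2.0 * math.pi * tau)


# ---------------------------------------------------------------------------
# Temperature dependence
# ---------------------------------------------------------------------------

_LAW_VALIDATORS = {
    "eps_inf": lambda v: np.all(v >= 0),
    "sigma_s": lambda v: np.all(v >= 0),
    "delta_eps": lambda v: np.all(v > 0),
    "tau": lambda v: np.all(v > 0),
    "alpha": lambda v: np.all((v >= 0) & (v < 1)),
}


@dataclass(frozen=True)
class TemperatureParameterLaw:
    """Polynomial law ``param(T)`` for one Cole–Cole parameter.

    ``coefficients`` are in ascending degree: ``(p0, p1)`` for a first-order
    law ``p1*T + p0`` or ``(q0, q1, q2)`` for a second-order one.  The tau
    law yields picoseconds (the printed convention); everything else is in
    its natural unit.  By default construction verifies that the law keeps
    its parameter physical over a dense grid of its validity range;
    data-driven laws (which may exit the physical region marginally at a
    range edge) can opt out with ``validate_physical=False`` — evaluation
    through :func:`model_at_temperature` clamps them back.
    """

    name: str
    order: int
    coefficients: tuple[float, ...]
    temp_range: tuple[float, float] = (20.0, 45.0)
    validate_physical: bool = True

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter name {self.name!r}")
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        coeffs = tuple(_check_finite(f"{self.name} coefficient", c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        if len(coeffs) != self.order + 1:
            raise ValueError(
                f"order {self.order} law needs {self.order + 1} coefficients, got {len(coeffs)}"
            )
        lo, hi = (float(t) for t in self.temp_range)
        if not lo < hi:
            raise ValueError(f"invalid temp_range {self.temp_range}")
        object.__setattr__(self, "temp_range", (lo, hi))
        if self.validate_physical:
            grid = np.linspace(lo, hi, 201)
            values = self(grid)
            if not _LAW_VALIDATORS[self.name](values):
                raise ValueError(
                    f"law for {self.name!r} leaves the physical range on [{lo}, {hi}] °C"
                )

    def __call__(self, T):
        """Evaluate the polynomial at temperature(s) ``T`` [°C]."""
        return np.polynomial.polynomial.polyval(np.asarray(T, dtype=float), self.coefficients)


@dataclass(frozen=True)
class TemperatureColeColeModel:
    """Single-pole Cole–Cole model whose five parameters follow polynomial
    temperature laws sharing one validity range."""

    laws: tuple[TemperatureParameterLaw, ...]
    label: str = ""

    def __post_init__(self) -> None:
        laws = tuple(self.laws)
        object.__setattr__(self, "laws", laws)
        names = [law.name for law in laws]
        if sorted(names) != sorted(PARAMETER_NAMES):
            raise ValueError(
                f"need exactly one law per parameter {PARAMETER_NAMES}, got {names}"
            )
        ranges = {law.temp_range for law in laws}
        if len(ranges) != 1:
            raise ValueError(f"laws disagree on temp_range: {sorted(ranges)}")

    @property
    def temp_range(self) -> tuple[float, float]:
        return self.laws[0].temp_range

    def law(self, name: str) -> TemperatureParameterLaw:
        for law in self.laws:
            if law.name == name:
                return law
        raise KeyError(name)

    def at_temperature(self, T: float, mode: str = "strict") -> ColeColeModel:
        return model_at_temperature(self, T, mode=mode)

    def evaluate(self, frequencies, T: float, mode: str = "strict") -> np.ndarray:
        return self.at_temperature(T, mode=mode).evaluate(frequencies)

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "temp_range_C": list(self.temp_range),
            "laws": {
                law.name: {
                    "order": law.order,
                    "coefficients": list(law.coefficients),
                    **({} if law.validate_physical else {"validate_physical": False}),
                }
                for law in self.laws
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TemperatureColeColeModel":
        rng = tuple(d.get("temp_range_C", (20.0, 45.0)))
        laws = tuple(
            TemperatureParameterLaw(
                name,
                spec["order"],
                tuple(spec["coefficients"]),
                rng,
                validate_physical=spec.get("validate_physical", True),
            )
            for name, spec in d["laws"].items()
        )
        return cls(laws, d.get("label", ""))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, path) -> "TemperatureColeColeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def model_at_temperature(
    tmodel: TemperatureColeColeModel, T: float, mode: str = "strict"
) -> ColeColeModel:
    """Instantiate the single-pole model at temperature ``T`` [°C].

    ``mode`` controls behaviour outside the validity range: ``"strict"``
    raises, ``"warn"`` extrapolates with a warning, ``"ignore"``
    extrapolates silently.  The tau law is converted from picoseconds to
    seconds here.  Evaluated parameters are clamped into their physical
    region (eps_inf, sigma_s >= 0; delta_eps, tau > 0; 0 <= alpha < 1), so
    data-driven laws that exit it marginally near a range edge still yield
    a valid passive model.
    """
    T = _check_finite("T", T)
    lo, hi = tmodel.temp_range
    if not lo <= T <= hi:
        if mode == "strict":
            raise ValueError(f"T = {T} °C outside validity range [{lo}, {hi}] °C")
        if mode == "warn":
            warnings.warn(
                f"T = {T} °C outside validity range [{lo}, {hi}] °C; extrapolating",
                stacklevel=2,
            )
        elif mode != "ignore":
            raise ValueError(f"unknown mode {mode!r}")
    params = {law.name: float(law(T)) for law in tmodel.laws}
    tiny = 1e-12
    pole = ColeColePole(
        max(params["delta_eps"], tiny),
        max(params["tau"], tiny) * 1e-12,
        min(max(params["alpha"], 0.0), np.nextafter(1.0, 0.0)),
    )
    return ColeColeModel(
        max(params["eps_inf"], 0.0), max(params["sigma_s"], 0.0), (pole,),
        label=f"{tmodel.label} @ {T:g} °C".strip(),
    )


def crossover_frequency(
    tmodel: TemperatureColeColeModel,
    T1: float,
    T2: float,
    f_lo: float,
    f_hi: float,
    mode: str = "strict",
    n_scan: int = 4096,
) -> float | None:
    """Frequency where the eps'(f) curves at two temperatures intersect.

    Scans ``g(f) = eps'(f, T1) - eps'(f, T2)`` on a log-spaced grid of
    ``n_scan`` points over ``[f_lo, f_hi]`` Hz; a unique sign change is
    refined by bisection to 1e-9 relative tolerance.  Returns ``None`` when
    no sign change exists and raises :class:`AmbiguousCrossoverError` when
    several do (listing the offending sub-brackets).
    """
    if T1 == T2:
        raise ValueError("T1 and T2 must differ")
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    m1 = model_at_temperature(tmodel, T1, mode=mode)
    m2 = model_at_temperature(tmodel, T2, mode=mode)

    def g(f):
        return np.real(m1.evaluate(f)) - np.real(m2.evaluate(f))

    grid = np.geomspace(f_lo, f_hi, n_scan)
    vals = g(grid)
    if np.all(vals == 0.0):
        return None  # curves identical on the bracket: no crossover
    zero = np.flatnonzero(vals == 0.0)
    if zero.size:
        # grid point is an exact root; treat as the (unique) crossover
        return float(grid[zero[0]])
    signs = np.sign(vals)
    flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    if flips.size == 0:
        return None
    if flips.size > 1:
        raise AmbiguousCrossoverError(
            [(float(grid[i]), float(grid[i + 1])) for i in flips]
        )
    i = flips[0]
    root = bisect(g, grid[i], grid[i + 1], rtol=1e-9, xtol=1e-6)
    return float(root)


# ---------------------------------------------------------------------------
# Published models
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> dict:
    with resources.files("thermodiel.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def literature_models() -> dict[str, ColeColeModel]:
    """The five muscle models at 37 °C from the packaged registry.

    Keys: ``Gabriel`` (2-pole gamma+delta), ``Peyman``, ``Abdilla``,
    ``Ley`` (2-pole), ``This work (37 °C)``.  All relaxation times are
    stored in seconds.
    """
    raw = _load_packaged("literature_muscle_37c.json")
    return {key: ColeColeModel.from_dict(entry) for key, entry in raw.items()}


def published_temperature_model(order: int = 1) -> TemperatureColeColeModel:
    """The packaged temperature-dependent muscle model (first- or
    second-order polynomial laws, valid 20–45 °C)."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    return TemperatureColeColeModel.from_dict(
        _load_packaged(f"muscle_temperature_model_order{order}.json")
    )
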