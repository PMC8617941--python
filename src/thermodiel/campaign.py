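"""Measurement containers: a single permittivity sweep and a campaign.

A sweep is one probe contact: a frequency grid with the measured complex
permittivity and the metadata the controlled setup records (actual sample
temperature, contact pressure, sample weights).  A campaign groups the
sweeps of a study — by default 8 set temperatures x 3 samples x 3 probing
sites — together with saline validation sweeps and an environment log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # avoid import cycle with uncertainty / models
    from .models import TemperatureColeColeModel
    from .uncertainty import ValidationPair

__all__ = ["FrequencySweep", "MeasurementCampaign"]


@dataclass
class FrequencySweep:
    """One dielectric measurement: grid, eps' and eps'' values, metadata."""

    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    actual_temperature: float
    set_temperature: Optional[float] = None
    sample_id: Optional[int] = None
    site_id: Optional[int] = None
    contact_pressure_kPa: Optional[float] = None
    weight_before_g: Optional[float] = None
    weight_after_g: Optional[float] = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.eps_imag = np.asarray(self.eps_imag, dtype=float)
        n = self.frequencies.size
        if self.eps_real.size != n or self.eps_imag.size != n:
            raise ValueError(
                f"length mismatch: {n} frequencies vs {self.eps_real.size} eps_real "
                f"/ {self.eps_imag.size} eps_imag values"
            )
        if n and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def eps_complex(self) -> np.ndarray:
        """``eps' - j eps''`` per frequency."""
        return self.eps_real - 1j * self.eps_imag

    @classmethod
    def from_complex(cls, frequencies, eps, **metadata) -> "FrequencySweep":
        eps = np.asarray(eps, dtype=complex)
        return cls(frequencies, eps.real, -eps.imag, **metadata)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_Hz": self.frequencies,
                "eps_real": self.eps_real,
                "eps_imag": self.eps_imag,
            }
        )

    @property
    def relative_weight_loss(self) -> Optional[float]:
        if self.weight_before_g is None or self.weight_after_g is None:
            return None
        return (self.weight_before_g - self.weight_after_g) / self.weight_before_g


@dataclass
class MeasurementCampaign:
    """A collection of sweeps plus optional validation data and truth model.

    ``truth`` holds the generating temperature model and is present exactly
    when the campaign is synthetic.
    """

    sweeps: list[FrequencySweep]
    validation: Optional["ValidationPair"] = None
    environment_log: Optional[pd.DataFrame] = None
    truth: Optional["TemperatureColeColeModel"] = None

    def __len__(self) -> int:
        return len(self.sweeps)

    @property
    def is_synthetic(self) -> bool:
        return self.truth is not None

    @property
    def set_temperatures(self) -> list[float]:
        seen: list[float] = []
        for sw in self.sweeps:
            t = sw.set_temperature
            if t is not None and t not in seen:
                seen.append(t)
        return seen

    def sweeps_at(self, set_temperature: float) -> list[FrequencySweep]:
        return [s for s in self.sweeps if s.set_temperature == set_temperature]
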