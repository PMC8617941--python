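"""Measurement-uncertainty budget from saline validation sweeps.

Before and after each measurement run a reference liquid (0.1 M NaCl in
the study design) is measured.  From those sweeps three per-frequency
components are estimated separately for eps' and eps'':

* random    — per-frequency sample standard deviation pooled within the pre
  and post groups (so a calibration drift between the groups does not
  masquerade as random scatter),
* systematic — |mean of all sweeps − reference-model prediction|,
* drift      — |mean(post) − mean(pre)|, the calibration ageing over the run,

combined in quadrature into ``s_comb = sqrt(random^2 + systematic^2 +
drift^2)``.  Error bars of ±1 s_comb feed the non-overlap significance
test: two measurements differ significantly at a frequency when their
intervals do not overlap, i.e. |m1 − m2| > s1 + s2 (touching bars do not
count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .campaign import FrequencySweep
from .models import ColeColeModel

__all__ = [
    "ValidationPair",
    "UncertaintyEstimate",
    "combined_uncertainty",
    "significant_difference",
]


@dataclass
class ValidationPair:
    """Pre- and post-run reference-liquid sweeps plus the reference model
    (the known permittivity of the liquid at its temperature)."""

    pre_sweeps: list[FrequencySweep]
    post_sweeps: list[FrequencySweep]
    reference: ColeColeModel

    def __post_init__(self) -> None:
        if not self.pre_sweeps or not self.post_sweeps:
            raise ValueError("need at least one pre and one post validation sweep")
        grid = self.pre_sweeps[0].frequencies
        for sw in [*self.pre_sweeps, *self.post_sweeps]:
            if sw.frequencies.shape != grid.shape or not np.array_equal(sw.frequencies, grid):
                raise ValueError("all validation sweeps must share one frequency grid")

    @property
    def frequencies(self) -> np.ndarray:
        return self.pre_sweeps[0].frequencies


@dataclass
class UncertaintyEstimate:
    """Per-frequency uncertainty components, split into eps'/eps'' tracks."""

    frequencies: np.ndarray
    random_re: np.ndarray
    random_im: np.ndarray
    systematic_re: np.ndarray
    systematic_im: np.ndarray
    drift_re: np.ndarray
    drift_im: np.ndarray
    scomb_re: np.ndarray
    scomb_im: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_Hz": self.frequencies,
                "random_re": self.random_re,
                "random_im": self.random_im,
                "systematic_re": self.systematic_re,
                "systematic_im": self.systematic_im,
                "drift_re": self.drift_re,
                "drift_im": self.drift_im,
                "scomb_re": self.scomb_re,
                "scomb_im": self.scomb_im,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stack(sweeps: Sequence[FrequencySweep]) -> tuple[np.ndarray, np.ndarray]:
    re = np.vstack([s.eps_real for s in sweeps])
    im = np.vstack([s.eps_imag for s in sweeps])
    return re, im


def _pooled_within_group_std(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Per-frequency sample sd pooled over groups: sqrt of the dof-weighted
    mean of within-group variances.  Zero when no group has >= 2 members
    (a single pre and post sweep carry no scatter information)."""
    dof = sum(g.shape[0] - 1 for g in groups)
    if dof == 0:
        return np.zeros(groups[0].shape[1])
    ss = sum(
        (g.shape[0] - 1) * np.var(g, axis=0, ddof=1)
        for g in groups
        if g.shape[0] > 1
    )
    return np.sqrt(ss / dof)


def combined_uncertainty(pair: ValidationPair) -> UncertaintyEstimate:
    """Random/systematic/drift decomposition of a validation pair.

    Requires at least two sweeps in total so the random component is a
    proper sample standard deviation.
    """
    n_total = len(pair.pre_sweeps) + len(pair.post_sweeps)
    if n_total < 2:
        raise ValueError("need >= 2 validation sweeps for a random component")
    pre_re, pre_im = _stack(pair.pre_sweeps)
    post_re, post_im = _stack(pair.post_sweeps)
    all_re = np.vstack([pre_re, post_re])
    all_im = np.vstack([pre_im, post_im])

    ref = pair.reference.evaluate(pair.frequencies)
    ref_re, ref_im = np.real(ref), -np.imag(ref)

    random_re = _pooled_within_group_std([pre_re, post_re])
    random_im = _pooled_within_group_std([pre_im, post_im])
    systematic_re = np.abs(all_re.mean(axis=0) - ref_re)
    systematic_im = np.abs(all_im.mean(axis=0) - ref_im)
    drift_re = np.abs(post_re.mean(axis=0) - pre_re.mean(axis=0))
    drift_im = np.abs(post_im.mean(axis=0) - pre_im.mean(axis=0))
    scomb_re = np.sqrt(random_re**2 + systematic_re**2 + drift_re**2)
    scomb_im = np.sqrt(random_im**2 + systematic_im**2 + drift_im**2)
    return UncertaintyEstimate(
        pair.frequencies.copy(),
        random_re, random_im,
        systematic_re, systematic_im,
        drift_re, drift_im,
        scomb_re, scomb_im,
    )


def significant_difference(mean1, s1, mean2, s2) -> np.ndarray:
    """Per-frequency non-overlap test on ±1 s_comb error bars.

    True where ``|mean1 - mean2| > s1 + s2``; exactly touching intervals
    are not significant.
    """
    mean1, s1, mean2, s2 = (np.asarray(a, dtype=float) for a in (mean1, s1, mean2, s2))
    if not (mean1.shape == s1.shape == mean2.shape == s2.shape):
        raise ValueError("means and uncertainties must share one grid shape")
    return np.abs(mean1 - mean2) > s1 + s2
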