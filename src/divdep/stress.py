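"""Diathesis-stress prevalence shapes.

Three Gaussian-family shapes over divorce-centred time t (months):

* stress-relief   — normal density right-truncated at t = -6 (depressogenic
  stress precedes the divorce decision and dissipates with it),
* stress-induction — normal density left-truncated at t = -6 (stress begins
  with the divorce decision),
* peak-stress     — untruncated normal (stress peaks around the divorce).

The -6 month truncation reflects the Finnish statutory six-month
consideration period between the divorce decision and its registration.
Each shape is standardised so its maximum over the evaluation grid is
exactly 1; the absolute scale is absorbed downstream by the fitted gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import GCurve

TRUNCATION_POINT = -6.0

TRUNCATIONS = ("right_at_minus6", "left_at_minus6", "none", "right_at_0")


@dataclass(frozen=True)
class StressShapeSpec:
    """Mode ``mu`` (months), dispersion ``sigma`` (months) and truncation."""

    mu: float
    sigma: float
    truncation: str = "none"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.truncation not in TRUNCATIONS:
            raise ValueError(f"unknown truncation {self.truncation!r}")


# model name -> truncation used when that family is fitted
FAMILY_TRUNCATION = {
    "stress_relief": "right_at_minus6",
    "stress_induction": "left_at_minus6",
    "peak_stress": "none",
}


def _support(truncation: str) -> tuple[float, float]:
    if truncation == "right_at_minus6":
        return (-np.inf, TRUNCATION_POINT)
    if truncation == "right_at_0":
        return (-np.inf, 0.0)
    if truncation == "left_at_minus6":
        return (TRUNCATION_POINT, np.inf)
    return (-np.inf, np.inf)


def stress_curve(grid: np.ndarray, spec: StressShapeSpec) -> GCurve:
    """Evaluate a (truncated) normal shape on ``grid``, max-standardised to 1.

    Truncation is a hard support restriction: values are exactly zero beyond
    the truncation point. The truncated density's normalising constant is
    irrelevant under max-standardisation.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = _support(spec.truncation)
    if lo == -np.inf and hi == np.inf:
        dens = stats.norm.pdf(grid, loc=spec.mu, scale=spec.sigma)
    else:
        a = (lo - spec.mu) / spec.sigma
        b = (hi - spec.mu) / spec.sigma
        dens = stats.truncnorm.pdf(grid, a, b, loc=spec.mu, scale=spec.sigma)
    dens = np.where(np.isfinite(dens), dens, 0.0)
    peak = float(np.max(dens))
    if peak <= 0.0:
        raise ValueError("all grid points lie outside the truncated support")
    return GCurve(grid, dens / peak, meta={"family": "stress", "spec": spec})
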