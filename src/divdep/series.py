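"""Core gridded containers: prevalence series and latent depression curves.

Everything downstream lives on a 3-month lattice. A divorce-centred window
of -60..+60 months at 3-month spacing has exactly 41 points; bins are
half-open ``[t, t+3)`` and labelled by their left edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIN_MONTHS = 3.0


def divorce_centred_grid(window: tuple[float, float] = (-60.0, 60.0)) -> np.ndarray:
    """Return the 3-month lattice of bin left edges covering ``window``.

    Both endpoints must be multiples of 3; the default -60..+60 window
    yields the canonical 41-point grid.
    """
    lo, hi = float(window[0]), float(window[1])
    if lo % BIN_MONTHS or hi % BIN_MONTHS:
        raise ValueError(f"window endpoints must be multiples of {BIN_MONTHS} months: {window}")
    if hi <= lo:
        raise ValueError("window must be increasing")
    return np.arange(lo, hi + BIN_MONTHS / 2, BIN_MONTHS)


def _check_lattice(times: np.ndarray, spacing: float | None = None) -> None:
    if times.ndim != 1 or times.size < 2:
        raise ValueError("grid must be a 1-d array with at least 2 points")
    steps = np.diff(times)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
        raise ValueError("grid must be strictly increasing with uniform spacing")
    if spacing is not None and not np.allclose(steps, spacing):
        raise ValueError(f"grid must have {spacing}-month spacing")


@dataclass
class PrevalenceSeries:
    """Binned purchase prevalence ``y(t)`` with per-bin denominators.

    ``times`` are months (divorce-centred or calendar, per ``centring``),
    ``values`` are proportions purchasing in each bin for raw series, or
    detrended/baseline-subtracted values once ``preprocessed`` is set.
    """

    times: np.ndarray
    values: np.ndarray
    denominators: np.ndarray
    centring: str = "divorce"
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.denominators = np.asarray(self.denominators, dtype=float)
        _check_lattice(self.times, BIN_MONTHS)
        if self.values.shape != self.times.shape or self.denominators.shape != self.times.shape:
            raise ValueError("times, values and denominators must share one shape")
        if self.centring not in ("divorce", "calendar"):
            raise ValueError(f"unknown centring {self.centring!r}")
        if np.any(self.denominators < 0):
            raise ValueError("denominators must be nonnegative")
        if not self.preprocessed and (np.any(self.values < 0) or np.any(self.values > 1)):
            raise ValueError("raw prevalence values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.times.size

    def copy_with(self, **kw) -> "PrevalenceSeries":
        return replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "prevalence": self.values,
                "denominator": self.denominators,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, centring: str = "divorce", preprocessed: bool | None = None
    ) -> "PrevalenceSeries":
        values = df["prevalence"].to_numpy(dtype=float)
        if preprocessed is None:
            # Raw prevalences are strictly positive proportions; a detrended,
            # baseline-subtracted series touches zero (or dips negative while
            # detrended-only). Used to auto-detect already-preprocessed files.
            preprocessed = bool(np.min(values) <= 1e-12)
        denom = (
            df["denominator"].to_numpy(dtype=float)
            if "denominator" in df
            else np.zeros(len(df))
        )
        return cls(
            times=df["time_months"].to_numpy(dtype=float),
            values=values,
            denominators=denom,
            centring=centring,
            preprocessed=preprocessed,
        )


@dataclass
class GCurve:
    """A latent depression-prevalence shape ``g(t)`` on the 3-month lattice.

    Diathesis-stress shapes are max-standardised to 1; the adaptive curve is
    a raw mode-prevalence whose maximum is already close to 1. The fitted
    gain absorbs any standardisation constant.
    """

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_lattice(self.times)
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must share one shape")
        if np.any(self.values < 0):
            raise ValueError("g-curve values must be nonnegative")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def max_standardised(self) -> "GCurve":
        peak = float(np.max(self.values))
        if peak <= 0:
            raise ValueError("cannot standardise an identically-zero curve")
        return GCurve(self.times, self.values / peak, dict(self.meta))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "g_value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "GCurve":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_months"].to_numpy(float), df["g_value"].to_numpy(float))
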