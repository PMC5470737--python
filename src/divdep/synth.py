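"""Synthetic prescription-register generator.

Access to the national registry behind the original prevalence series is
legally restricted, so this module generates individual-level purchase
records with the statistical structure the analysis assumes: a cohort with
divorced and never-divorced strata, a linear secular trend in background
antidepressant purchasing, divorce-locked depressive episodes whose onset
distribution follows a configurable latent shape, and exponentially decaying
treatment persistence. Every downstream stage (binning, detrending, fitting,
model comparison) is thereby testable end to end, including parameter
recovery against known ground truth.

Scale defaults mirror the register study: a cohort of 304,112 individuals of
whom 23,956 divorced, observed over a 156-month window, purchases aggregated
to 3-month bins.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .series import BIN_MONTHS, GCurve, divorce_centred_grid
from .stress import FAMILY_TRUNCATION, StressShapeSpec, stress_curve

REGISTRY_N = 304_112
REGISTRY_N_DIVORCED = 23_956

EPISODE_MODELS = ("stress_relief", "stress_induction", "peak_stress", "adaptive_curve")


@dataclass
class CohortConfig:
    """Ground-truth configuration of the synthetic register.

    ``episode_model`` selects the onset-distribution family for
    divorce-locked depressive episodes; for the three stress families the
    shape is parameterised by (``episode_mu``, ``episode_sigma``) in months,
    for ``adaptive_curve`` a precomputed :class:`GCurve` must be supplied.
    The shape is renormalised to a discrete density over the divorce-centred
    grid before sampling onsets.

    ``episode_probability`` is the probability that a divorcee has a
    divorce-locked episode (a free generator knob: the registry does not
    identify episodes). Given an episode, treatment starts with probability
    ``response_alpha`` in the onset bin and continues bin-to-bin with
    probability exp(-3 * ``persistence_lambda``), a geometric discretisation
    of exponential decay with per-month rate ``persistence_lambda``.
    Background purchases occur independently in each calendar bin with
    probability ``background_rate`` + ``trend_slope`` * month.
    """

    n_individuals: int = REGISTRY_N
    divorced_fraction: float = REGISTRY_N_DIVORCED / REGISTRY_N
    study_months: int = 156
    episode_model: str = "stress_relief"
    episode_mu: float = -6.0
    episode_sigma: float = 4.5
    episode_curve: GCurve | None = None
    episode_probability: float = 0.06
    persistence_lambda: float = 0.04
    response_alpha: float = 1.0
    background_rate: float = 0.02
    trend_slope: float = 0.00015
    drug_class_tags: dict[str, float] | None = None
    seed: int = 0
    window: tuple[float, float] = (-60.0, 60.0)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("divorced_fraction", "episode_probability", "response_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.persistence_lambda <= 0:
            raise ValueError("persistence_lambda must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if self.background_rate + self.trend_slope * self.study_months > 1.0:
            raise ValueError("background rate exceeds 1 at end of study window")
        if self.trend_slope < 0 and self.background_rate + self.trend_slope * self.study_months < 0:
            raise ValueError("background rate becomes negative within study window")
        if self.episode_model not in EPISODE_MODELS:
            raise ValueError(f"unknown episode_model {self.episode_model!r}")
        if self.episode_model == "adaptive_curve" and self.episode_curve is None:
            raise ValueError("adaptive_curve episode model requires episode_curve")
        lo, hi = self.window
        if hi - lo > self.study_months:
            raise ValueError("divorce-centred window does not fit inside study_months")
        if self.drug_class_tags is not None:
            w = np.array(list(self.drug_class_tags.values()), dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("drug_class_tags weights must be nonnegative and sum to 1")

    @property
    def n_divorced(self) -> int:
        return int(round(self.divorced_fraction * self.n_individuals))

    def episode_density(self) -> GCurve:
        """The episode-onset shape renormalised to a discrete density."""
        grid = divorce_centred_grid(self.window)
        if self.episode_model == "adaptive_curve":
            curve = self.episode_curve
            if not np.array_equal(curve.times, grid):
                raise ValueError("episode_curve grid must match the divorce-centred window")
            vals = curve.values
        else:
            spec = StressShapeSpec(
                self.episode_mu, self.episode_sigma, FAMILY_TRUNCATION[self.episode_model]
            )
            vals = stress_curve(grid, spec).values
        total = vals.sum()
        if total <= 0:
            raise ValueError("episode shape is identically zero on the grid")
        return GCurve(grid, vals / total, meta={"normalised": "density"})

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.episode_curve is not None:
            d["episode_curve"] = {
                "time_months": self.episode_curve.times.tolist(),
                "g_value": self.episode_curve.values.tolist(),
            }
        d["window"] = list(self.window)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if d.get("episode_curve") is not None:
            ec = d["episode_curve"]
            d["episode_curve"] = GCurve(
                np.asarray(ec["time_months"], float), np.asarray(ec["g_value"], float)
            )
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, src) -> "CohortConfig":
        if hasattr(src, "read"):
            data = yaml.safe_load(src)
        else:
            with open(src) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclass
class PurchaseTable:
    """Individual-level purchase records.

    ``persons`` has one row per individual (person_id, divorce_month — NaN
    for the never-divorced stratum — and drug_class); ``purchases`` is long
    format with one row per (person_id, purchase_month). Purchase months lie
    inside [0, study_months).
    """

    persons: pd.DataFrame
    purchases: pd.DataFrame
    study_months: int
    seed: int | None = None

    def __post_init__(self) -> None:
        pm = self.purchases["purchase_month"]
        if len(pm) and (pm.min() < 0 or pm.max() >= self.study_months):
            raise ValueError("purchase months outside [0, study_months)")

    @property
    def n_individuals(self) -> int:
        return len(self.persons)

    @property
    def divorced_ids(self) -> np.ndarray:
        return self.persons.loc[self.persons["divorce_month"].notna(), "person_id"].to_numpy()

    def to_csv(self, path) -> None:
        """Long-format CSV (person_id, divorce_month, purchase_month, drug_class)."""
        merged = self.purchases.merge(self.persons, on="person_id", how="left")
        cols = ["person_id", "divorce_month", "purchase_month", "drug_class"]
        buf = io.StringIO()
        buf.write(f"# seed={self.seed} study_months={self.study_months}\n")
        merged[cols].to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def _sample_episode_bins(
    rng: np.random.Generator, cfg: CohortConfig, divorce_month: np.ndarray
) -> list[np.ndarray]:
    """Per divorcee: the divorce-centred calendar bins with episode purchases."""
    density = cfg.episode_density()
    n_div = divorce_month.size
    has_episode = rng.random(n_div) < cfg.episode_probability
    treated = has_episode & (rng.random(n_div) < cfg.response_alpha)
    onset_rel = np.full(n_div, np.nan)
    idx = rng.choice(density.n, size=int(treated.sum()), p=density.values)
    onset_rel[treated] = density.times[idx]
    # geometric continuation: bin-to-bin survival exp(-lambda * 3 months)
    cont = np.exp(-cfg.persistence_lambda * BIN_MONTHS)
    n_bins_total = cfg.study_months // int(BIN_MONTHS)
    out: list[np.ndarray] = []
    for i in range(n_div):
        if not treated[i]:
            out.append(np.empty(0, dtype=int))
            continue
        onset_cal = divorce_month[i] + onset_rel[i]
        k = int(rng.geometric(1.0 - cont)) - 1  # extra bins beyond the onset bin
        bins = (onset_cal / BIN_MONTHS).astype(int) + np.arange(k + 1)
        bins = bins[(bins >= 0) & (bins < n_bins_total)]
        out.append(bins)
    return out


def generate_cohort(config: CohortConfig) -> PurchaseTable:
    """Generate a synthetic register cohort; deterministic for a fixed seed.

    Divorcees receive a divorce month uniform over the 3-month lattice points
    for which the full divorce-centred window fits inside the study span.
    Episode purchases start at the sampled onset bin and continue with
    geometric persistence; background purchases occur independently per
    calendar bin at the trending background rate. Purchase months are drawn
    uniformly inside their bin.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_div = config.n_divorced
    lo, hi = config.window
    if n_div < 1:
        raise ValueError("divorced stratum is empty; increase divorced_fraction")
    person_id = np.arange(n)
    # admissible divorce months: window must fit inside [0, study_months)
    # last divorce-centred bin [d+hi, d+hi+3) must still fit inside the span
    lattice = np.arange(-lo, config.study_months - hi - BIN_MONTHS + 0.5, BIN_MONTHS)
    if lattice.size == 0:
        raise ValueError("no admissible divorce months inside study window")
    divorce_month = rng.choice(lattice, size=n_div)
    n_bins = config.study_months // int(BIN_MONTHS)
    bin_months = np.arange(n_bins) * BIN_MONTHS

    # background purchases, all individuals x calendar bins
    p_bg = np.clip(config.background_rate + config.trend_slope * bin_months, 0.0, 1.0)
    bg = rng.random((n, n_bins)) < p_bg[None, :]

    # episode purchases for divorcees
    ep_bins = _sample_episode_bins(rng, config, divorce_month)
    for i, bins in enumerate(ep_bins):
        bg[i, bins] = True  # divorcees occupy ids 0..n_div-1

    pid, b = np.nonzero(bg)
    # uniform month within the 3-month bin keeps binning nontrivial
    month = bin_months[b] + rng.integers(0, int(BIN_MONTHS), size=pid.size)

    div_col = np.full(n, np.nan)
    div_col[:n_div] = divorce_month
    if config.drug_class_tags:
        labels = list(config.drug_class_tags)
        weights = np.array([config.drug_class_tags[k] for k in labels], float)
        drug = rng.choice(labels, size=n, p=weights / weights.sum())
    else:
        drug = np.full(n, None, dtype=object)
    persons = pd.DataFrame(
        {"person_id": person_id, "divorce_month": div_col, "drug_class": drug}
    )
    purchases = pd.DataFrame({"person_id": pid, "purchase_month": month.astype(float)})
    return PurchaseTable(persons, purchases, config.study_months, seed=config.seed)


def true_parameter_record(config: CohortConfig) -> dict:
    """Ground-truth parameters used by the generator, for recovery tests."""
    record = {
        "episode_model": config.episode_model,
        "lambda": config.persistence_lambda,
        "alpha_equivalent_gain": config.episode_probability * config.response_alpha,
        "episode_probability": config.episode_probability,
        "response_alpha": config.response_alpha,
        "background_rate": config.background_rate,
        "trend_slope": config.trend_slope,
        "n_individuals": config.n_individuals,
        "n_divorced": config.n_divorced,
        "seed": config.seed,
    }
    if config.episode_model == "adaptive_curve":
        record["episode_curve"] = config.episode_curve
    else:
        record["mu"] = config.episode_mu
        record["sigma"] = config.episode_sigma
    return record
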