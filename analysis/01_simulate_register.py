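"""Generate the register-scale synthetic cohort and its preprocessed series.

Emulates the study population: 304,112 individuals (23,956 divorced)
observed over 156 months, purchases in 3-month bins, a rising secular trend
in background purchasing, and divorce-locked episodes with a stress-relief
onset distribution (mode -6 months, dispersion 4.5 months). Writes the
41-point preprocessed divorce-centred series used by the model-comparison
scripts, and the raw divorced/control series for inspection.
"""

from pathlib import Path

import numpy as np

from divdep import (
    CohortConfig,
    bin_prevalence,
    detrend_and_baseline,
    generate_cohort,
    wald_interval,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "data"
RESULTS = ROOT / "results"

FIXTURE_SEED = 20170614


def main() -> None:
    DATA.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = CohortConfig(seed=FIXTURE_SEED)
    print(f"cohort: {cfg.n_individuals:,} individuals, {cfg.n_divorced:,} divorced")
    table = generate_cohort(cfg)
    print(f"purchase events: {len(table.purchases):,}")

    divorced = bin_prevalence(table, centring="divorce")
    control = bin_prevalence(table, centring="calendar")
    series = detrend_and_baseline(divorced, control)

    peak_idx = int(np.argmax(divorced.values))
    p, n = divorced.values[peak_idx], divorced.denominators[peak_idx]
    lo, hi = wald_interval(p, n)
    print(
        f"raw divorced prevalence peaks at t={divorced.times[peak_idx]:+.0f} months: "
        f"{p:.4f} (95% Wald CI {lo:.4f}-{hi:.4f})"
    )
    print(
        f"control series drifts from {control.values[0]:.4f} to {control.values[-1]:.4f} "
        "over the study span"
    )
    print(f"preprocessed series: {series.n} points, min {series.values.min()} (exactly 0)")

    cfg.to_yaml(DATA / "synthetic_cohort_config.yaml")
    series.to_csv(DATA / "synthetic_prevalence_fixture.csv")
    divorced.to_csv(RESULTS / "divorced_raw_series.csv")
    control.to_csv(RESULTS / "control_calendar_series.csv")
    print(f"wrote {DATA / 'synthetic_prevalence_fixture.csv'}")


if __name__ == "__main__":
    main()
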