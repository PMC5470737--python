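"""Solve the adaptive life-history model and extract its prediction curve.

Backward-induction dynamic programming finds when the depressed mode u1
maximises reproductive value; a 50,000-individual forward simulation of the
optimal (error-prone) strategy yields the divorce-centred prevalence of u1,
the adaptive model's latent depression curve g4. Also reports the
high-mortality counterfactual (z = 0.06) under which the depressed mode is
never adaptive.
"""

from pathlib import Path

import numpy as np

from divdep import LifeHistoryParams, adaptive_g, simulate_population, solve_strategy
from divdep.adaptive import AT_RISK, measured_annual_divorce_hazard

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SIM_SEED = 77


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = LifeHistoryParams()
    print(
        f"environment: m={params.m:.6f}, z={params.z}, s={params.s}, "
        f"rho={params.rho:.6f}, d1=d2={params.d1}, delta={params.delta}, T={params.T}"
    )
    strategy, values = solve_strategy(params)
    u1 = strategy.u1_optimal()
    print(
        f"depressed mode optimal in 'relationship at risk' for {u1[AT_RISK].sum()} of "
        f"{params.T} periods (never while seeking or married)"
    )
    print(f"reproductive values at t=0: {np.round(values.V[:, 0], 2)}")

    high_z, _ = solve_strategy(LifeHistoryParams(z=0.06))
    print(
        f"with z=0.06 the depressed mode is optimal in {high_z.u1_optimal().sum()} "
        "state-periods: not adaptive under any circumstances"
    )

    sim = simulate_population(strategy, params, 50_000, seed=SIM_SEED)
    print(f"simulated 50,000 individuals; cumulative mortality {(sim.states[:, -1] == 3).mean():.4f}")
    print(f"measured annual divorce hazard among intact couples: "
          f"{measured_annual_divorce_hazard(sim):.4f}")

    g4 = adaptive_g(sim)
    print(
        f"g4 from {g4.meta['n_events']:,} usable divorce events; "
        f"peak {g4.values.max():.4f} at t={g4.times[np.argmax(g4.values)]:+.0f} months "
        "(after the 3-month leftward registration-lag shift)"
    )

    strategy.to_frame().to_csv(RESULTS / "adaptive_strategy.csv")
    values.to_frame().to_csv(RESULTS / "adaptive_values.csv")
    g4.to_csv(RESULTS / "adaptive_g4.csv")
    print(f"wrote {RESULTS / 'adaptive_g4.csv'}")


if __name__ == "__main__":
    main()
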