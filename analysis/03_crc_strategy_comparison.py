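"""Simulate the synthetic colorectal model and compare all 20 strategies.

Runs the full grid of colonoscopy strategies against no screening under
default assumptions (average mortality, no background costs/disutility),
reports incremental cost, LY and QALY per 1000 40-year-olds, and the
efficient frontier of the synthetic model.  Writes
results/crc/strategy_table.csv.

The absolute magnitudes are those of the synthetic natural history, not of
any calibrated model; the point of this driver is the shape of the
comparison, not the numbers themselves.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from screencea import synthetic_data as sd
from screencea.cea import CEPoint, efficient_frontier
from screencea.economics import CancerCareParams, ScenarioAssumptions, summarize_arm
from screencea.natural_history import simulate_cohort
from screencea.population_inputs import fit_age_curve
from screencea.screening import run_arm

OUT = Path(__file__).resolve().parents[1] / "results" / "crc"
SEED = 12345
N = 20_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SyntheticConfig(seed=SEED)
    life = sd.make_life_table(cfg)
    params = sd.crc_like_params()
    care = CancerCareParams()
    scen = ScenarioAssumptions.default()

    t0 = time.perf_counter()
    cohort = simulate_cohort(N, params, life, 1.0, SEED, entry_age=40.0)
    print(f"simulated {N} natural histories in {time.perf_counter()-t0:.0f}s; "
          f"{np.mean([h.died_of_cancer for h in cohort]):.1%} die of cancer unscreened")

    results = {}
    for strat in [sd.no_screening()] + sd.default_strategy_grid("crc_like"):
        arm = run_arm(cohort, strat, SEED, params)
        results[strat.label] = summarize_arm(arm, None, None, care, scen, strat.label)
    ref = results["No screening"]

    rows = []
    points = []
    for label, r in results.items():
        rows.append({"strategy": label,
                     "d_cost_mln": (r.cost - ref.cost) / 1e6,
                     "d_ly": r.ly - ref.ly, "d_qaly": r.qaly - ref.qaly})
        points.append(CEPoint(label=label, cost=r.cost - ref.cost, qaly=r.qaly - ref.qaly))
    rep = efficient_frontier(points, comparator_label="No screening")
    df = pd.DataFrame(rows)
    df["label"] = df.strategy.map(rep.labels)
    df["icer"] = df.strategy.map(rep.icers)
    df.to_csv(OUT / "strategy_table.csv", index=False)

    eff = [p.label for p in rep.efficient if p.label != "No screening"]
    print(f"synthetic-model frontier ({len(eff)} efficient strategies):")
    for label in eff:
        icer = rep.icers.get(label)
        print(f"  {label}: " + (f"ICER ${icer:,.0f}/QALY" if icer else "reference"))


if __name__ == "__main__":
    main()
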