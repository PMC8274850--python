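"""Generate the synthetic model inputs and fit the population age curves.

Writes the life table, the weighted expenditure and utility observations,
the fitted age curves, and the evaluated strategy grids to results/inputs/,
and prints the headline features of each input (life expectancy, curve
parameters, grid sizes).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from screencea import synthetic_data as sd
from screencea.population_inputs import fit_age_curve

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SEED = 12345


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SyntheticConfig(seed=SEED)

    life = sd.make_life_table(cfg)
    le = np.trapezoid(life.survival, life.ages)
    median = life.quantile_conditional(0.5, 0.0)
    sd.write_life_table_csv(life, OUT / "life_table.csv")
    print(f"life table: expectancy {le:.1f} y, median lifespan {median:.1f} y, "
          f"S(110)={life.survival[-1]:.1e}")

    costs = sd.make_cost_observations(cfg)
    utils = sd.make_utility_observations(cfg)
    sd.write_series_csv(costs, OUT / "cost_observations.csv")
    sd.write_series_csv(utils, OUT / "utility_observations.csv")

    cost_curve = fit_age_curve(costs, "exponential")
    util_curve = fit_age_curve(utils, "linear", clip_unit=True)
    pd.DataFrame(
        [
            {"curve": "cost", "form": cost_curve.form,
             "parameters": list(cost_curve.parameters), "weighted_sse": cost_curve.sse},
            {"curve": "utility", "form": util_curve.form,
             "parameters": list(util_curve.parameters), "weighted_sse": util_curve.sse},
        ]
    ).to_csv(OUT / "fitted_curves.csv", index=False)
    a, b = cost_curve.parameters
    print(f"expenditure curve: {a:.0f}*exp({b:.4f}*age) $/person-year "
          f"(${cost_curve(40):,.0f} at 40, ${cost_curve(85):,.0f} at 85)")
    u0, u1 = util_curve.parameters
    print(f"utility curve: {u0:.3f} {u1:+.5f}*age "
          f"({util_curve(40):.3f} at 40, {util_curve(85):.3f} at 85)")

    for disease in ("crc_like", "eac_like"):
        grid = sd.default_strategy_grid(disease)
        sd.write_strategy_grid_csv(grid, OUT / f"strategies_{disease}.csv")
        print(f"{disease}: {len(grid)} screening strategies")
    sd.write_config_yaml(cfg, OUT / "synthetic_config.yaml")


if __name__ == "__main__":
    main()
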