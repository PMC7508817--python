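"""Sensitivity of the plant sink fraction to concentration outliers.

Quarterly sampling means one anomalous sample can move the annual mean
concentration substantially. This analysis compares sink fractions
computed from mean- versus median-aggregated concentrations on synthetic
quarterly series where each sample has a 25% chance of being a 10x
outlier. Finding: outlier-free replicates shift by only a few percentage
points (pure seasonal spread between mean and median), while a 10x
outlier moves the mean-based sink fraction by tens of points — which is
why the median basis is exposed as an explicit sensitivity switch rather
than silently substituted.
"""

from datetime import date
from pathlib import Path

import pandas as pd

from floatload import io
from floatload.budget import (
    ConcentrationSample,
    PlantNutrientPool,
    compound_envelope,
    sensitivity_mean_vs_median,
)
from floatload.synthetic import ConcentrationModel, ScenarioConfig, gen_concentration_samples

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20180301


def main() -> None:
    rows = []
    pool = PlantNutrientPool("P", 5.0, *compound_envelope(5.0, 0.13, 0.076))
    for rep in range(20):
        cfg = ScenarioConfig(
            seed=SEED + rep,
            concentration=ConcentrationModel(outlier_prob=0.25, outlier_factor=10.0),
        )
        df = gen_concentration_samples(cfg)
        # same seed without outliers reuses identical noise draws, so a diff
        # against it identifies exactly which replicates carried an outlier
        clean_df = gen_concentration_samples(
            ScenarioConfig(seed=SEED + rep, concentration=ConcentrationModel())
        )
        samples = [
            ConcentrationSample("river", date(2018, 3, 1), float(r.tp_ugL), float(r.tn_ugL))
            for r in df.itertuples()
        ]
        delta = sensitivity_mean_vs_median(samples, pool, q_mean_m3s=2.0)
        rows.append({"replicate": rep, "delta_pp": delta,
                     "had_outlier": bool((df["tp_ugL"] != clean_df["tp_ugL"]).any())})
    res = pd.DataFrame(rows)
    io.write_table(res, OUT / "outlier_sensitivity.csv",
                   comments=["mean-minus-median sink fraction, percentage points"])
    print(res.round(3).to_string(index=False))
    clean = res.loc[~res["had_outlier"], "delta_pp"].abs().max()
    dirty = res.loc[res["had_outlier"], "delta_pp"].abs().max()
    print(
        f"largest mean-vs-median shift: {clean:.2f} pp without outliers, "
        f"{dirty:.2f} pp with a 10x outlier present"
    )
    print(f"wrote {OUT / 'outlier_sensitivity.csv'}")


if __name__ == "__main__":
    main()
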