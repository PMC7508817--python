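"""Area-discharge rating curve: fit, predictions and parameter recovery.

Fits Q = a * A^b to the synthetic gauge network from 01 and predicts
mean discharge for the three small study catchments; then runs 500 noisy
replicates to verify the exponent is recovered without bias. Finding:
under lognormal scatter (sigma = 0.2, 20 stations) the mean recovered
exponent sits within a few thousandths of the truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from floatload import io
from floatload.hydrology import GaugeStation, fit_rating_curve, predict_discharge
from floatload.synthetic import ScenarioConfig, gen_gauges

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20180301
STUDY_AREAS = {"Chongwe": 5130.0, "Little Chongwe": 530.0, "Maramba": 510.0}


def _stations(df):
    return [
        GaugeStation(str(r.station_id), float(r.area_km2), float(r.q_mean_m3s))
        for r in df.itertuples()
    ]


def main() -> None:
    cfg = ScenarioConfig(seed=SEED)
    curve = fit_rating_curve(_stations(gen_gauges(cfg)))
    print(
        f"fitted Q = {curve.coef_a:.4g} * A^{curve.exponent_b:.4g} "
        f"(n={curve.n_stations}, log-RMSE={curve.log_space_rmse:.3f})"
    )
    rows = [
        {"site": site, "area_km2": area, "q_pred_m3s": predict_discharge(curve, area)}
        for site, area in STUDY_AREAS.items()
    ]
    pred = pd.DataFrame(rows)
    print(pred.round(3).to_string(index=False))

    rng = np.random.default_rng(SEED)
    g = cfg.gauges
    slopes = []
    for _ in range(500):
        ar = np.exp(rng.uniform(np.log(100), np.log(50_000), g.n_stations))
        q = g.coef_a * ar**g.exponent_b * np.exp(rng.normal(0, g.noise_sigma, g.n_stations))
        slopes.append(
            fit_rating_curve(
                [GaugeStation(f"r{i}", x, y) for i, (x, y) in enumerate(zip(ar, q))]
            ).exponent_b
        )
    print(
        f"exponent recovery over 500 replicates: mean {np.mean(slopes):.4f} "
        f"(truth {g.exponent_b}), sd {np.std(slopes):.4f}"
    )
    io.write_table(pred, OUT / "rating_predictions.csv",
                   comments=["discharge predicted from catchment area via power-law rating curve"])
    print(f"wrote {OUT / 'rating_predictions.csv'}")


if __name__ == "__main__":
    main()
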