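"""Generate every input the downstream analyses consume.

Writes two bundles under results/inputs/:
  * demo/      - the observed per-tributary study inputs (discharge,
                 peak vegetation area, mean concentrations, landcover);
  * synthetic/ - a seeded synthetic scenario (trait records, gauge
                 network, monthly cover series, quarterly concentrations,
                 landcover grids) used for the verification analyses.
"""

from pathlib import Path

from floatload import io
from floatload.synthetic import ScenarioConfig, gen_concentration_samples, gen_cover_series, gen_gauges, gen_landcover, gen_trait_records, zambezi_demo

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 20180301  # first sampling campaign date


def main() -> None:
    demo = zambezi_demo()
    for name, df in demo.items():
        io.write_table(df, OUT / "demo" / f"{name}.csv")

    cfg = ScenarioConfig(seed=SEED)
    syn = OUT / "synthetic"
    io.write_table(gen_trait_records(cfg), syn / "traits.csv")
    io.write_table(gen_gauges(cfg), syn / "gauges.csv")
    io.write_table(gen_cover_series(cfg), syn / "cover.csv")
    io.write_table(gen_concentration_samples(cfg), syn / "concentrations.csv")
    grid, mask = gen_landcover(cfg)
    io.write_ascii_grid(grid.values, grid.pixel_size_m, syn / "urban.asc")
    io.write_ascii_grid(mask.member.astype(float), grid.pixel_size_m, syn / "mask.asc")
    print(f"wrote observed demo bundle and synthetic scenario (seed {SEED}) under {OUT}")


if __name__ == "__main__":
    main()
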