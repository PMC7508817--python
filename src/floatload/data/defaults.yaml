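# Default trait synthesis values for Water Hyacinth (Eichhornia crassipes).
#
# These are calibrated stand-in values for a literature synthesis of floating
# dry biomass per unit cover area and tissue nutrient content: the primary
# literature tables behind the published synthesis are not distributed with
# this package, so the means and relative standard errors below were solved
# to reproduce the published per-area nutrient densities and confidence
# intervals. Override any of them with a user trait CSV for a real synthesis.
#
# Units: biomass_per_area in kg dry weight per m^2 of cover;
#        n_content / p_content as fractions of dry weight.
year_seconds: 31536000
traits:
  biomass_per_area:
    mean: 2.0
    rel_se: 0.13
    n_studies: 15
  p_content:
    mean: 0.004836
    rel_se: 0.076
    n_studies: 17
  n_content:
    mean: 0.02391
    rel_se: 0.09
    n_studies: 14
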