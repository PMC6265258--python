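# Default vital-rate parameters for the two larch species.
# Calibrated (not transcribed): sibirica grows and disperses faster but is
# markedly more sensitive to competition and needs a slightly longer
# growing season; gmelinii is slower but competition- and cold-tolerant.
# With these defaults, dense warm stands exclude sibirica while sparse
# cold stands (below roughly 100 trees/ha) admit both species.
version: 2
species:
  sibirica:
    height_growth_max: 0.40   # m/yr
    gdd_min: 220.0            # degC day
    gdd_halfsat: 180.0
    comp_sens_growth: 0.08
    comp_sens_estab: 1.8
    comp_mort_coeff: 0.08
    fecundity: 20.0           # seeds per m above maturity per yr
    maturity_height: 2.0      # m
    dispersal_mean: 12.0      # m
    estab_prob: 0.06
    background_mort: 0.02
    seed_mort: 0.5
    max_seed_age: 2
    max_age: 400
    max_height: 30.0
  gmelinii:
    height_growth_max: 0.25   # m/yr
    gdd_min: 200.0
    gdd_halfsat: 180.0
    comp_sens_growth: 0.04
    comp_sens_estab: 0.12
    comp_mort_coeff: 0.008
    fecundity: 20.0
    maturity_height: 2.0
    dispersal_mean: 8.0
    estab_prob: 0.06
    background_mort: 0.015
    seed_mort: 0.5
    max_seed_age: 2
    max_age: 500
    max_height: 25.0
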