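# Allometric model bank for coastal-redwood biomass estimation.
#
# Two kinds of entries:
#
# * published — the widely-used US generalised log-log models, with their
#   published coefficients (diameter in cm, mass in kg).
# * synthetic stand-in — species-specific redwood models whose original
#   coefficient tables are not distributed with this package.  Each carries
#   the stated functional form and predictor set of the model it stands in
#   for, with coefficients calibrated once against the analytic stem family
#   of tlstree.synthetic (see scripts/calibrate_standin_models.py).  They
#   are suitable for exercising the pipeline and for synthetic-cohort
#   studies, NOT for predicting real-tree biomass.
#
# Diameter predictors: DBH (least-squares circle at 1.2-1.4 m), fDBH
# (equivalent-area diameter of the alpha-shape section), DTB (circle at
# 4.0-4.5 m, above buttress).  H = highest point above lowest point.
# Wood density 380 kg/m^3 (basic-density class of Sequoia sempervirens).

models:
  - model_id: parks
    form: volume_density
    predictors: [DBH, H]
    coefficients: {a: 0.438872, b_DBH: 2.02182, b_H: 0.878308}
    wood_density_kg_m3: 380.0
    predictor_unit: m
    response: volume_m3
    source: "synthetic stand-in (species-specific DBH,H volume model; calibrated on the tlstree analytic stem family)"

  - model_id: fujimori
    form: volume_density
    predictors: [DBH, H]
    coefficients: {a: 0.291534, b_DBH: 1.97337, b_H: 0.986683}
    wood_density_kg_m3: 380.0
    predictor_unit: m
    response: volume_m3
    source: "synthetic stand-in (species-specific D^2H volume model; calibrated on the tlstree analytic stem family)"

  - model_id: sillett2015
    form: volume_density
    predictors: [DTB, fDBH]
    coefficients: {a: 21.4602, b_DTB: 1.96688, b_fDBH: 0.395962}
    wood_density_kg_m3: 380.0
    predictor_unit: m
    response: volume_m3
    source: "synthetic stand-in (crown-mapping-style DTB,fDBH volume model; calibrated on the tlstree analytic stem family)"

  - model_id: sillett2019
    form: volume_density
    predictors: [DTB, H]
    coefficients: {a: 1.163, b_DTB: 2.01553, b_H: 0.750057}
    wood_density_kg_m3: 380.0
    predictor_unit: m
    response: volume_m3
    source: "synthetic stand-in (ground-measurement DTB,H volume model; calibrated on the tlstree analytic stem family)"

  - model_id: kizha_han
    form: log_log
    predictors: [DBH]
    coefficients: {b0: -2.61541, b1: 2.42776}
    correction_factor: 1.008
    predictor_unit: cm
    response: agb_kg
    source: "synthetic stand-in (destructive-harvest-style DBH-only model with back-transformation correction factor; calibrated on the tlstree analytic stem family)"

  - model_id: jenkins
    form: log_log
    predictors: [DBH]
    coefficients: {b0: -2.0336, b1: 2.2592}
    predictor_unit: cm
    response: agb_kg
    source: "Jenkins et al. 2003, For. Sci. 49(1), national-scale US biomass equations, cedar/larch softwood group"

  - model_id: chojnacky
    form: log_log
    predictors: [DBH]
    coefficients: {b0: -2.7765, b1: 2.4195}
    predictor_unit: cm
    response: agb_kg
    source: "Chojnacky et al. 2014, Forestry 87, updated generalized biomass equations, Cupressaceae 0.30-0.39 specific-gravity group"
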