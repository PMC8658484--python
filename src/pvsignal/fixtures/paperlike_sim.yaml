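# Simulation mimicking the demographic and exposure structure of a
# published spontaneous-report angioedema screen at 1/10 scale.
n_cases: 53429
baseline_event_prob: 0.02
seed: 20211125
sex_probs: {female: 0.54, male: 0.46}
age_band_probs: {'<40': 0.14, '40-49': 0.09, '50-59': 0.14, '60-69': 0.22, '70-79': 0.23, '80-89': 0.14, '>=90': 0.04}
exclusion_noise: {subjective_age: 0.02, missing_sex: 0.01, missing_age: 0.02}
drug_specs:
  - {name: alacepril, exposure_prob: 3.93047e-05, reporting_ratio: 7.14286, drug_class: ace_inhibitors}
  - {name: benazepril, exposure_prob: 2.43315e-05, reporting_ratio: 3.84615, drug_class: ace_inhibitors}
  - {name: captopril, exposure_prob: 0.000117914, reporting_ratio: 1.5873, drug_class: ace_inhibitors}
  - {name: cilazapril, exposure_prob: 2.24598e-05, reporting_ratio: 4.16667, drug_class: ace_inhibitors}
  - {name: delapril, exposure_prob: 1.87165e-05, reporting_ratio: 0, drug_class: ace_inhibitors}
  - {name: enalapril, exposure_prob: 0.00144304, reporting_ratio: 5.57717, drug_class: ace_inhibitors}
  - {name: imidapril, exposure_prob: 0.000544651, reporting_ratio: 8.24742, drug_class: ace_inhibitors}
  - {name: lisinopril, exposure_prob: 0.00024893, reporting_ratio: 6.39098, drug_class: ace_inhibitors}
  - {name: perindopril, exposure_prob: 0.000213368, reporting_ratio: 2.63158, drug_class: ace_inhibitors}
  - {name: quinapril, exposure_prob: 5.61496e-05, reporting_ratio: 1.66667, drug_class: ace_inhibitors}
  - {name: temocapril, exposure_prob: 0.000196524, reporting_ratio: 3.33333, drug_class: ace_inhibitors}
  - {name: trandolapril, exposure_prob: 6.17646e-05, reporting_ratio: 6.06061, drug_class: ace_inhibitors}
  - {name: alogliptin, exposure_prob: 0.00118476, reporting_ratio: 1.18483, drug_class: dpp4_inhibitors}
  - {name: anagliptin, exposure_prob: 0.00039679, reporting_ratio: 0.471698, drug_class: dpp4_inhibitors}
  - {name: linagliptin, exposure_prob: 0.00137754, reporting_ratio: 0.543478, drug_class: dpp4_inhibitors}
  - {name: omarigliptin, exposure_prob: 0.000245187, reporting_ratio: 0, drug_class: dpp4_inhibitors}
  - {name: saxagliptin, exposure_prob: 0.00041925, reporting_ratio: 0.223214, drug_class: dpp4_inhibitors}
  - {name: sitagliptin, exposure_prob: 0.00398849, reporting_ratio: 0.610042, drug_class: dpp4_inhibitors}
  - {name: teneligliptin, exposure_prob: 0.00109866, reporting_ratio: 0.340716, drug_class: dpp4_inhibitors}
  - {name: trelagliptin, exposure_prob: 0.000310694, reporting_ratio: 1.20482, drug_class: dpp4_inhibitors}
  - {name: vildagliptin, exposure_prob: 0.00408582, reporting_ratio: 1.03069, drug_class: dpp4_inhibitors}
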