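{
  "description": "Trastuzumab IV-to-SC reformulation scenario: three-weekly dosing (17.33 administrations/year), chronic indication; the SC formulation is sold bundled with an injection device. Coefficients are the identity-Gaussian GLM fit of the full cost model; subgroup smearing factors as used in the IV/SC cost predictions.",
  "coefficient_set": {
    "model_id": "C",
    "estimator": "glm_identity_gaussian",
    "se_source": "robust",
    "coefficients": {
      "intercept": 7.1499,
      "subcutaneous": -3.2026,
      "intramuscular": -5.2737,
      "dosfreq": 0.428,
      "productbund": 0.404,
      "indicatn": -0.2896,
      "dosfreq_sq": -0.00106,
      "dosfreq_x_indicatn": -0.3173
    },
    "se": {
      "intercept": 0.349,
      "subcutaneous": 0.363,
      "intramuscular": 0.509,
      "dosfreq": 0.054,
      "productbund": 0.269,
      "indicatn": 0.183,
      "dosfreq_sq": 0.0002,
      "dosfreq_x_indicatn": 0.028
    },
    "smearing": {
      "normal_theory": 1.4252,
      "duan": 1.204,
      "subgroup": {
        "IV": 1.0792,
        "SC": 1.3799,
        "IM": 1.0
      },
      "wooldridge": 1.0287,
      "selected": "subgroup"
    }
  },
  "scenario_iv": {
    "route": "IV",
    "indication": "chronic",
    "bundled": 0,
    "dosfreq": 17.33
  },
  "scenario_sc": {
    "route": "SC",
    "indication": "chronic",
    "bundled": 1,
    "dosfreq": 17.33
  },
  "regimen": {
    "interval_value": 3,
    "interval_unit": "week"
  },
  "expected": {
    "ln_cost_iv": 8.4604,
    "ln_cost_sc": 5.6618,
    "cost_iv": 5097.99,
    "cost_sc": 396.94,
    "saving_per_patient_floor": 4700,
    "cohort_size": 200,
    "cohort_saving": 940200
  }
}
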