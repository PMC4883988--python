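{
  "se_source": "robust",
  "estimators": {
    "glm_log_gamma": {
      "coefficients": {
        "intercept": 7.3703,
        "subcutaneous": -2.8255,
        "intramuscular": -5.0158,
        "dosfreq": 0.4015,
        "productbund": 0.2364,
        "indicatn": -0.2352,
        "dosfreq_sq": -0.00102,
        "dosfreq_x_indicatn": -0.3004
      },
      "se": {
        "intercept": 0.257,
        "subcutaneous": 0.314,
        "intramuscular": 0.393,
        "dosfreq": 0.042,
        "productbund": 0.198,
        "indicatn": 0.145,
        "dosfreq_sq": 0.0002,
        "dosfreq_x_indicatn": 0.021
      },
      "stats": {
        "loglik": -143.3921,
        "aic": 16.377,
        "delta": 1.589,
        "delta_ci": [1.251, 1.921]
      }
    },
    "pglm_eee_qv": {
      "coefficients": {
        "intercept": -0.6008,
        "subcutaneous": -2.6618,
        "intramuscular": -4.7495,
        "dosfreq": 0.3754,
        "productbund": 0.2336,
        "indicatn": -0.2592,
        "dosfreq_sq": -0.00093,
        "dosfreq_x_indicatn": -0.2775
      },
      "se": {
        "intercept": 0.264,
        "subcutaneous": 0.369,
        "intramuscular": 0.609,
        "dosfreq": 0.059,
        "productbund": 0.19,
        "indicatn": 0.133,
        "dosfreq_sq": 0.0001,
        "dosfreq_x_indicatn": 0.053
      },
      "stats": {
        "lambda": 0.078,
        "lambda_ci": [-0.2361, 0.3921],
        "theta1": 0.0304,
        "theta1_ci": [-0.0038, 0.0646],
        "theta2": 0.0899,
        "theta2_ci": [-0.0038, 0.1836]
      }
    },
    "glm_identity_gaussian": {
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
      "stats": {
        "loglik": -16.8641,
        "aic": 2.3182,
        "r2": 0.8923,
        "adj_r2": 0.8285
      }
    },
    "nlls": {
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
        "intercept": 0.455,
        "subcutaneous": 0.474,
        "intramuscular": 0.664,
        "dosfreq": 0.07,
        "productbund": 0.35,
        "indicatn": 0.283,
        "dosfreq_sq": 0.0003,
        "dosfreq_x_indicatn": 0.036
      },
      "stats": {
        "r2": 0.8923,
        "adj_r2": 0.8692
      }
    }
  }
}
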