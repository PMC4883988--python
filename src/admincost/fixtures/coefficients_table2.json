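{
  "se_source": "default",
  "models": {
    "A": {
      "coefficients": {
        "intercept": 8.6223,
        "subcutaneous": -3.2858,
        "intramuscular": -2.4097,
        "dosfreq": -0.0046
      },
      "se": {
        "intercept": 0.45,
        "subcutaneous": 0.57,
        "intramuscular": 0.9,
        "dosfreq": 0.011
      },
      "stats": {
        "r2": 0.7188,
        "adj_r2": 0.6586,
        "f_stat": 11.9313,
        "f_crit": 3.1122,
        "ssr": 17.8023,
        "n": 18,
        "se_ln": 1.1276,
        "f_ratio_vs_C": 3.781,
        "f_ratio_crit": 3.478
      }
    },
    "B": {
      "coefficients": {
        "intercept": 9.6888,
        "subcutaneous": -2.6161,
        "intramuscular": -2.2784,
        "dosfreq": -0.0025,
        "productbund": -0.7395,
        "indicatn": -1.0527
      },
      "se": {
        "intercept": 1.274,
        "subcutaneous": 1.106,
        "intramuscular": 1.219,
        "dosfreq": 0.012,
        "productbund": 1.129,
        "indicatn": 1.219
      },
      "stats": {
        "r2": 0.7376,
        "adj_r2": 0.627,
        "f_stat": 6.7151,
        "f_crit": 2.9961,
        "ssr": 16.6714,
        "n": 18,
        "se_ln": 1.1787,
        "f_ratio_vs_C": 6.764,
        "f_ratio_crit": 4.1028
      }
    },
    "C": {
      "coefficients": {
        "intercept": 7.1058,
        "subcutaneous": -3.2073,
        "intramuscular": -5.1856,
        "dosfreq": 0.4206,
        "productbund": 0.4133,
        "indicatn": -0.2084,
        "dosfreq_sq": -0.00105,
        "dosfreq_x_indicatn": -0.3126
      },
      "se": {
        "intercept": 1.521,
        "subcutaneous": 0.902,
        "intramuscular": 1.335,
        "dosfreq": 0.18,
        "productbund": 0.928,
        "indicatn": 1.467,
        "dosfreq_sq": 0.0003,
        "dosfreq_x_indicatn": 0.172
      },
      "stats": {
        "r2": 0.8881,
        "adj_r2": 0.8098,
        "f_stat": 11.3369,
        "f_crit": 3.0717,
        "ssr": 7.0858,
        "n": 18,
        "se_ln": 0.8418
      }
    },
    "D": {
      "coefficients": {
        "intercept": 11.305,
        "dosfreq": -0.1022,
        "productbund": -2.7416,
        "indicatn": -3.7195,
        "dosfreq_sq": -0.00075,
        "dosfreq_x_indicatn": 0.17
      },
      "se": {
        "intercept": 1.685,
        "dosfreq": 0.179,
        "productbund": 0.678,
        "indicatn": 1.693,
        "dosfreq_sq": 0.0004,
        "dosfreq_x_indicatn": 0.183
      },
      "stats": {
        "r2": 0.6957,
        "adj_r2": 0.5689,
        "f_stat": 5.4864,
        "f_crit": 2.9961,
        "ssr": 19.2688,
        "n": 18,
        "se_ln": 1.2672,
        "f_ratio_vs_C": 10.3161,
        "f_ratio_crit": 4.1028
      }
    }
  }
}
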