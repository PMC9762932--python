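{
  "counts": {
    "n_removed_frequency": 0,
    "n_removed_impact": 0,
    "n_removed_qc": 0,
    "n_samples_in": 60,
    "n_samples_retained": 60,
    "n_variants_in": 5,
    "n_variants_retained": 5
  },
  "meta": {
    "config_hash": "de18362f712fede3",
    "seed": 7
  },
  "policy": {
    "four_gene": {
      "ci_lower": 0.6836378621576497,
      "ci_upper": 0.895309506263403,
      "missed": 44.536263891679354,
      "missed_rounded": 45,
      "per_sex": {
        "female": {
          "missed": 19.21652773311866,
          "total": 21.01399206189677
        },
        "male": {
          "missed": 25.319736158560687,
          "total": 36.10452213122933
        }
      },
      "proportion": 0.7797167787154913,
      "total": 57.1185141931261,
      "total_rounded": 57
    },
    "genomics_england": {
      "ci_lower": 0.753855689671221,
      "ci_upper": 0.9218199860044547,
      "missed": 61.65616889724425,
      "missed_rounded": 62,
      "per_sex": {
        "female": {
          "missed": 24.225545460517793,
          "total": 26.023009789295898
        },
        "male": {
          "missed": 37.430623436726464,
          "total": 48.2154094093951
        }
      },
      "proportion": 0.8305156489422043,
      "total": 74.23841919869099,
      "total_rounded": 74
    }
  },
  "yield": {
    "four_gene": [
      {
        "age_group": "<40",
        "ci_lower": 1.0,
        "ci_upper": 1.0,
        "k": 1,
        "n": 1,
        "p": 1.0,
        "panel": "four_gene"
      },
      {
        "age_group": "40-49",
        "ci_lower": -0.17434465027856438,
        "ci_upper": 0.6743446502785644,
        "k": 1,
        "n": 4,
        "p": 0.25,
        "panel": "four_gene"
      },
      {
        "age_group": "50-59",
        "ci_lower": 0.0,
        "ci_upper": 0.0,
        "k": 0,
        "n": 13,
        "p": 0.0,
        "panel": "four_gene"
      },
      {
        "age_group": "60-69",
        "ci_lower": -0.007037138362025741,
        "ci_upper": 0.27976441108929845,
        "k": 3,
        "n": 22,
        "p": 0.13636363636363635,
        "panel": "four_gene"
      },
      {
        "age_group": ">=70",
        "ci_lower": -0.04551682940272121,
        "ci_upper": 0.1455168294027212,
        "k": 1,
        "n": 20,
        "p": 0.05,
        "panel": "four_gene"
      }
    ],
    "genomics_england": [
      {
        "age_group": "<40",
        "ci_lower": 1.0,
        "ci_upper": 1.0,
        "k": 1,
        "n": 1,
        "p": 1.0,
        "panel": "genomics_england"
      },
      {
        "age_group": "40-49",
        "ci_lower": -0.17434465027856438,
        "ci_upper": 0.6743446502785644,
        "k": 1,
        "n": 4,
        "p": 0.25,
        "panel": "genomics_england"
      },
      {
        "age_group": "50-59",
        "ci_lower": -0.06792865278562824,
        "ci_upper": 0.2217748066317821,
        "k": 1,
        "n": 13,
        "p": 0.07692307692307693,
        "panel": "genomics_england"
      },
      {
        "age_group": "60-69",
        "ci_lower": 0.02064962464472833,
        "ci_upper": 0.34298673899163534,
        "k": 4,
        "n": 22,
        "p": 0.18181818181818182,
        "panel": "genomics_england"
      },
      {
        "age_group": ">=70",
        "ci_lower": -0.04551682940272121,
        "ci_upper": 0.1455168294027212,
        "k": 1,
        "n": 20,
        "p": 0.05,
        "panel": "genomics_england"
      }
    ]
  }
}
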