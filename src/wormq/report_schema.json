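{
  "$defs": {
    "Comparison": {
      "properties": {
        "strain_a": {
          "title": "Strain A",
          "type": "string"
        },
        "strain_b": {
          "title": "Strain B",
          "type": "string"
        },
        "quantity": {
          "title": "Quantity",
          "type": "string"
        },
        "t": {
          "title": "T",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "number"
        },
        "p_raw": {
          "title": "P Raw",
          "type": "number"
        },
        "p_adj": {
          "title": "P Adj",
          "type": "number"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        }
      },
      "required": [
        "strain_a",
        "strain_b",
        "quantity",
        "t",
        "df",
        "p_raw",
        "p_adj",
        "significant"
      ],
      "title": "Comparison",
      "type": "object"
    },
    "RegressionSummary": {
      "properties": {
        "x_quantity": {
          "title": "X Quantity",
          "type": "string"
        },
        "y_quantity": {
          "title": "Y Quantity",
          "type": "string"
        },
        "intercept": {
          "title": "Intercept",
          "type": "number"
        },
        "slope": {
          "title": "Slope",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "n_points": {
          "title": "N Points",
          "type": "integer"
        }
      },
      "required": [
        "x_quantity",
        "y_quantity",
        "intercept",
        "slope",
        "r_squared",
        "n_points"
      ],
      "title": "RegressionSummary",
      "type": "object"
    },
    "StrainSummary": {
      "properties": {
        "strain": {
          "title": "Strain",
          "type": "string"
        },
        "n_animals": {
          "title": "N Animals",
          "type": "integer"
        },
        "mean_sleep_fraction": {
          "title": "Mean Sleep Fraction",
          "type": "number"
        },
        "sem_sleep_fraction": {
          "title": "Sem Sleep Fraction",
          "type": "number"
        },
        "mean_ris_baseline": {
          "title": "Mean Ris Baseline",
          "type": "number"
        },
        "mean_rim_inactivity_fraction": {
          "title": "Mean Rim Inactivity Fraction",
          "type": "number"
        }
      },
      "required": [
        "strain",
        "n_animals",
        "mean_sleep_fraction",
        "sem_sleep_fraction",
        "mean_ris_baseline",
        "mean_rim_inactivity_fraction"
      ],
      "title": "StrainSummary",
      "type": "object"
    },
    "SurvivalComparisonRow": {
      "properties": {
        "strain": {
          "title": "Strain",
          "type": "string"
        },
        "day_tested": {
          "title": "Day Tested",
          "type": "integer"
        },
        "alive": {
          "title": "Alive",
          "type": "integer"
        },
        "dead": {
          "title": "Dead",
          "type": "integer"
        },
        "p_raw": {
          "title": "P Raw",
          "type": "number"
        },
        "p_adj": {
          "title": "P Adj",
          "type": "number"
        },
        "significant": {
          "title": "Significant",
          "type": "boolean"
        },
        "t50_fit": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "T50 Fit"
        },
        "k_fit": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "K Fit"
        },
        "A_fit": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "A Fit"
        },
        "converged": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Converged"
        }
      },
      "required": [
        "strain",
        "day_tested",
        "alive",
        "dead",
        "p_raw",
        "p_adj",
        "significant"
      ],
      "title": "SurvivalComparisonRow",
      "type": "object"
    }
  },
  "description": "Schema of the report's summary.json.",
  "properties": {
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "preset": {
      "additionalProperties": true,
      "title": "Preset",
      "type": "object"
    },
    "version": {
      "title": "Version",
      "type": "string"
    },
    "n_animals_processed": {
      "title": "N Animals Processed",
      "type": "integer"
    },
    "n_animals_failed": {
      "title": "N Animals Failed",
      "type": "integer"
    },
    "strains": {
      "items": {
        "$ref": "#/$defs/StrainSummary"
      },
      "title": "Strains",
      "type": "array"
    },
    "comparisons": {
      "items": {
        "$ref": "#/$defs/Comparison"
      },
      "title": "Comparisons",
      "type": "array"
    },
    "regression": {
      "anyOf": [
        {
          "$ref": "#/$defs/RegressionSummary"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "survival": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/SurvivalComparisonRow"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Survival"
    },
    "survival_reference_day": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Survival Reference Day"
    }
  },
  "required": [
    "seed",
    "preset",
    "version",
    "n_animals_processed",
    "n_animals_failed",
    "strains",
    "comparisons"
  ],
  "title": "ReportSummary",
  "type": "object"
}
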