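{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dta-meta analysis report",
  "type": "object",
  "required": ["metadata", "arms", "comparison", "warnings"],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["package_version", "input_path", "input_sha256", "generated_at", "config"],
      "properties": {
        "package_version": {"type": "string"},
        "input_path": {"type": "string"},
        "input_sha256": {"type": "string"},
        "generated_at": {"type": "string"},
        "config": {
          "type": "object",
          "required": ["model", "correction_mode", "correction_value", "ci_level", "moses_weighted", "auc_range", "auc_grid_step", "spearman_scale"]
        }
      }
    },
    "arms": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["test_label", "k", "studies", "pooled", "sroc", "threshold", "deeks", "leave_one_out"],
        "properties": {
          "test_label": {"type": "string"},
          "k": {"type": "integer"},
          "studies": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["study_id", "tp", "fp", "fn", "tn", "corrected", "sens", "spec", "plr", "nlr", "dor"],
              "properties": {
                "study_id": {"type": "string"},
                "tp": {"type": "integer"},
                "fp": {"type": "integer"},
                "fn": {"type": "integer"},
                "tn": {"type": "integer"},
                "corrected": {"type": "boolean"},
                "sens": {"type": "number"},
                "spec": {"type": "number"},
                "plr": {"type": "number"},
                "nlr": {"type": "number"},
                "dor": {"type": "number"}
              }
            }
          },
          "pooled": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["measure", "model", "estimate", "ci_low", "ci_high", "k", "cochran_q", "df", "p_het", "i_squared", "tau_squared"],
              "properties": {
                "measure": {"type": "string"},
                "model": {"type": "string"},
                "estimate": {"type": "number"},
                "ci_low": {"type": "number"},
                "ci_high": {"type": "number"},
                "k": {"type": "integer"},
                "cochran_q": {"type": "number"},
                "df": {"type": "integer"},
                "p_het": {"type": ["number", "null"]},
                "i_squared": {"type": "number"},
                "tau_squared": {"type": "number"}
              }
            }
          },
          "sroc": {
            "type": ["object", "null"],
            "required": ["a", "b", "weighted", "k", "auc", "se_auc", "q_star", "se_q_star"],
            "properties": {
              "a": {"type": "number"},
              "b": {"type": "number"},
              "se_a": {"type": ["number", "null"]},
              "se_b": {"type": ["number", "null"]},
              "cov_ab": {"type": ["number", "null"]},
              "weighted": {"type": "boolean"},
              "k": {"type": "integer"},
              "auc": {"type": "number"},
              "se_auc": {"type": ["number", "null"]},
              "q_star": {"type": "number"},
              "se_q_star": {"type": ["number", "null"]}
            }
          },
          "threshold": {
            "type": ["object", "null"],
            "required": ["rho", "p_value", "scale", "k"]
          },
          "deeks": {
            "type": ["object", "null"],
            "required": ["slope", "intercept", "p_value", "ess", "k"]
          },
          "leave_one_out": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["excluded_study_id", "sens", "spec", "plr", "nlr", "dor"]
            }
          }
        }
      }
    },
    "comparison": {
      "type": ["object", "null"],
      "required": ["arm1", "arm2", "q_star", "auc"],
      "properties": {
        "arm1": {"type": "string"},
        "arm2": {"type": "string"},
        "q_star": {
          "type": ["object", "null"],
          "required": ["z", "p_value", "statistic_compared"]
        },
        "auc": {
          "type": ["object", "null"],
          "required": ["z", "p_value", "statistic_compared"]
        }
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
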