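{
  "schema": {
    "properties": {
      "config_hash": {
        "type": "string"
      },
      "schema_version": {
        "type": "number"
      },
      "seed": {
        "type": "number"
      },
      "studies": {
        "items": {
          "properties": {
            "discs": {
              "items": {
                "properties": {
                  "level": {
                    "type": "string"
                  },
                  "tasks": {
                    "type": "object"
                  }
                },
                "required": [
                  "level",
                  "tasks"
                ],
                "type": "object"
              },
              "type": "array"
            },
            "instances": {
              "items": {
                "properties": {
                  "centroid_mm": {
                    "items": {
                      "type": "number"
                    },
                    "type": "array"
                  },
                  "confidence": {
                    "type": "number"
                  },
                  "level": {
                    "type": "string"
                  },
                  "skip_before": {
                    "type": "boolean"
                  },
                  "transitional": {
                    "type": "boolean"
                  }
                },
                "required": [
                  "level",
                  "centroid_mm",
                  "confidence"
                ],
                "type": "object"
              },
              "type": "array"
            },
            "study_id": {
              "type": "string"
            },
            "timings_s": {
              "type": "object"
            },
            "warnings": {
              "items": {
                "type": "string"
              },
              "type": "array"
            }
          },
          "required": [
            "study_id",
            "instances",
            "discs",
            "timings_s",
            "warnings"
          ],
          "type": "object"
        },
        "type": "array"
      },
      "tool_version": {
        "type": "string"
      }
    },
    "required": [
      "schema_version",
      "tool_version",
      "config_hash",
      "seed",
      "studies"
    ],
    "type": "object"
  },
  "schema_version": 1
}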