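{
  "$defs": {
    "DiagnosticReference": {
      "additionalProperties": false,
      "properties": {
        "ai_pct": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Ai Pct"
        },
        "event_counts": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Event Counts",
          "type": "object"
        },
        "severe": {
          "title": "Severe",
          "type": "boolean"
        },
        "severe_threshold_pct": {
          "title": "Severe Threshold Pct",
          "type": "number"
        },
        "window_end_s": {
          "title": "Window End S",
          "type": "number"
        },
        "window_s": {
          "title": "Window S",
          "type": "number"
        }
      },
      "required": [
        "window_end_s",
        "window_s",
        "ai_pct",
        "severe",
        "severe_threshold_pct",
        "event_counts"
      ],
      "title": "DiagnosticReference",
      "type": "object"
    },
    "VentilatorParameters": {
      "additionalProperties": false,
      "properties": {
        "fio2_pct": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Fio2 Pct"
        },
        "minute_ventilation_l_per_min": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Minute Ventilation L Per Min"
        },
        "peak_pressure_cmh2o": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Peak Pressure Cmh2O"
        },
        "peep_cmh2o": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Peep Cmh2O"
        },
        "tidal_volume_ml": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tidal Volume Ml"
        },
        "total_rr_per_min": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Total Rr Per Min"
        }
      },
      "title": "VentilatorParameters",
      "type": "object"
    },
    "WaveformExcerpt": {
      "additionalProperties": false,
      "properties": {
        "end_index": {
          "title": "End Index",
          "type": "integer"
        },
        "start_index": {
          "title": "Start Index",
          "type": "integer"
        }
      },
      "required": [
        "start_index",
        "end_index"
      ],
      "title": "WaveformExcerpt",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Analysis report for one sliding-window snapshot.",
  "properties": {
    "basic_info": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Basic Info",
      "type": "object"
    },
    "diagnostic_reference": {
      "$ref": "#/$defs/DiagnosticReference"
    },
    "prompts_findings": {
      "items": {
        "type": "string"
      },
      "title": "Prompts Findings",
      "type": "array"
    },
    "ventilator_parameters": {
      "$ref": "#/$defs/VentilatorParameters"
    },
    "waveform_excerpt": {
      "$ref": "#/$defs/WaveformExcerpt"
    }
  },
  "required": [
    "basic_info",
    "diagnostic_reference",
    "prompts_findings",
    "ventilator_parameters",
    "waveform_excerpt"
  ],
  "title": "AnalysisReport",
  "type": "object"
}
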