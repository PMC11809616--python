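{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "posturekit:session-log:1.0",
  "title": "posturekit session log",
  "description": "One monitored stage: an OpenMHealth-style envelope with a header (schema id/version, subject, stage label, config snapshot, calibration reference) and a body (1 Hz angle records and all feedback events). Body timestamps are seconds since stage start; event ISO-8601 timestamps are derived from header.start_time on write.",
  "type": "object",
  "required": ["header", "body"],
  "properties": {
    "header": {
      "type": "object",
      "required": ["schema_id", "schema_version", "subject_id", "stage", "start_time", "config"],
      "properties": {
        "schema_id": {"const": "posturekit:session-log"},
        "schema_version": {"const": "1.0"},
        "subject_id": {"type": "string"},
        "stage": {"enum": ["feedback_on", "feedback_off"]},
        "start_time": {"type": "string", "format": "date-time"},
        "config": {
          "type": "object",
          "properties": {
            "frontal_threshold_deg": {"type": "number", "exclusiveMinimum": 0},
            "lateral_threshold_deg": {"type": "number", "exclusiveMinimum": 0},
            "tolerance_s": {"type": "number", "minimum": 0},
            "vibration_enabled": {"type": "boolean"},
            "audio_enabled": {"type": "boolean"},
            "visual_enabled": {"type": "boolean"},
            "language": {"enum": ["en", "es", "pt"]},
            "hysteresis_deg": {"type": "number", "minimum": 0},
            "directive_repeat_s": {"type": ["number", "null"], "exclusiveMinimum": 0},
            "praise_interval_s": {"type": "number", "exclusiveMinimum": 0},
            "rng_seed": {"type": "integer"}
          }
        },
        "calibration": {
          "type": ["object", "null"],
          "required": ["r0"],
          "properties": {
            "r0": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
            "created_at": {"type": "number"}
          }
        }
      }
    },
    "body": {
      "type": "object",
      "required": ["angle_records", "events"],
      "properties": {
        "angle_records": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["t", "frontal_deg", "lateral_deg", "posture"],
            "properties": {
              "t": {"type": "number", "minimum": 0},
              "frontal_deg": {"type": "number", "exclusiveMinimum": -180, "maximum": 180},
              "lateral_deg": {"type": "number", "exclusiveMinimum": -180, "maximum": 180},
              "posture": {"enum": ["IN_POSTURE", "OUT_OF_POSTURE"]}
            }
          }
        },
        "events": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["t", "kind"],
            "properties": {
              "t": {"type": "number", "minimum": 0},
              "timestamp": {"type": "string", "format": "date-time"},
              "kind": {
                "enum": ["COLOR_GREEN", "COLOR_RED", "VIBRATION", "AUDIO_DIRECTIVE",
                         "AUDIO_PRAISE", "AUDIO_CONGRATULATION", "CALIBRATED",
                         "SETTINGS_CHANGED", "MONITORING_STARTED", "MONITORING_PAUSED"]
              },
              "payload": {"type": ["object", "null"]}
            }
          }
        }
      }
    }
  }
}
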