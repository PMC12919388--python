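{
  "$defs": {
    "Branch": {
      "properties": {
        "target": {
          "minLength": 1,
          "title": "Target",
          "type": "string"
        },
        "probability": {
          "anyOf": [
            {
              "maximum": 1.0,
              "minimum": 0.0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Probability"
        },
        "predicate": {
          "anyOf": [
            {
              "$ref": "#/$defs/Predicate"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "target"
      ],
      "title": "Branch",
      "type": "object"
    },
    "CodedConcept": {
      "description": "A clinical code from one of the three vocabularies the pathway uses:\nSNOMED-CT for conditions/findings, CUPS (Colombia's unified procedure\nclassification) for procedures, CIE-10 (Spanish ICD-10) for diagnoses.",
      "properties": {
        "system": {
          "enum": [
            "SNOMED-CT",
            "CIE-10",
            "CUPS"
          ],
          "title": "System",
          "type": "string"
        },
        "code": {
          "minLength": 1,
          "title": "Code",
          "type": "string"
        },
        "display": {
          "default": "",
          "title": "Display",
          "type": "string"
        }
      },
      "required": [
        "system",
        "code"
      ],
      "title": "CodedConcept",
      "type": "object"
    },
    "Predicate": {
      "description": "Attribute test attached to a Conditional branch.",
      "properties": {
        "attribute": {
          "minLength": 1,
          "title": "Attribute",
          "type": "string"
        },
        "operator": {
          "default": "==",
          "enum": [
            "==",
            "!="
          ],
          "title": "Operator",
          "type": "string"
        },
        "value": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "integer"
            },
            {
              "type": "number"
            },
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Value"
        }
      },
      "required": [
        "attribute"
      ],
      "title": "Predicate",
      "type": "object"
    },
    "State": {
      "properties": {
        "kind": {
          "$ref": "#/$defs/StateKind"
        },
        "codes": {
          "default": [],
          "items": {
            "$ref": "#/$defs/CodedConcept"
          },
          "title": "Codes",
          "type": "array"
        },
        "weeks": {
          "anyOf": [
            {
              "minimum": 0,
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Weeks"
        },
        "attribute": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Attribute"
        },
        "value": {
          "anyOf": [
            {
              "type": "boolean"
            },
            {
              "type": "integer"
            },
            {
              "type": "number"
            },
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Value"
        },
        "transition": {
          "anyOf": [
            {
              "$ref": "#/$defs/Transition"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        }
      },
      "required": [
        "kind"
      ],
      "title": "State",
      "type": "object"
    },
    "StateKind": {
      "enum": [
        "Initial",
        "Simple",
        "Delay",
        "Encounter",
        "ConditionOnset",
        "ConditionEnd",
        "Procedure",
        "Observation",
        "SetAttribute",
        "Death",
        "Terminal"
      ],
      "title": "StateKind",
      "type": "string"
    },
    "Transition": {
      "description": "Outgoing edge set of a state.\n\n- ``Direct``: exactly one branch, taken unconditionally.\n- ``Distributed``: branch drawn at random; probabilities must sum to 1.\n- ``Conditional``: branches evaluated in declared order against the\n  person's attributes; the last branch must be a catch-all (no\n  predicate) so a walk can never dead-end.",
      "properties": {
        "mode": {
          "enum": [
            "Direct",
            "Distributed",
            "Conditional"
          ],
          "title": "Mode",
          "type": "string"
        },
        "branches": {
          "items": {
            "$ref": "#/$defs/Branch"
          },
          "minItems": 1,
          "title": "Branches",
          "type": "array"
        }
      },
      "required": [
        "mode",
        "branches"
      ],
      "title": "Transition",
      "type": "object"
    }
  },
  "description": "Named directed graph of typed clinical states.\n\nStructural shape is enforced here (pydantic); graph-level invariants \u2014\nexactly one Initial, no dangling targets, probability mass, catch-alls,\nreachability \u2014 are audited by :func:`validate_module` so that a\nmalformed in-memory module can still be inspected and reported on.",
  "properties": {
    "name": {
      "minLength": 1,
      "title": "Name",
      "type": "string"
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "initial": {
      "minLength": 1,
      "title": "Initial",
      "type": "string"
    },
    "states": {
      "additionalProperties": {
        "$ref": "#/$defs/State"
      },
      "title": "States",
      "type": "object"
    }
  },
  "required": [
    "name",
    "initial",
    "states"
  ],
  "title": "ModuleDefinition",
  "type": "object"
}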