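{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pathviz diagram exchange format",
  "type": "object",
  "required": ["schemaVersion", "pathwayId", "canvas", "nodes", "edges"],
  "properties": {
    "schemaVersion": {"const": 1},
    "pathwayId": {"type": "string", "minLength": 1},
    "canvas": {"$ref": "#/$defs/rect"},
    "nodes": {"type": "array", "items": {"$ref": "#/$defs/node"}},
    "edges": {"type": "array", "items": {"$ref": "#/$defs/edge"}},
    "compartments": {"type": "array", "items": {"$ref": "#/$defs/compartment"}},
    "subpathways": {"$ref": "#/$defs/subpathways"}
  },
  "$defs": {
    "rect": {
      "type": "object",
      "required": ["x", "y", "w", "h"],
      "properties": {
        "x": {"type": "number"},
        "y": {"type": "number"},
        "w": {"type": "number", "minimum": 0},
        "h": {"type": "number", "minimum": 0}
      }
    },
    "point": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 2,
      "maxItems": 2
    },
    "node": {
      "type": "object",
      "required": ["id", "schemaClass", "displayName", "bounds"],
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "schemaClass": {
          "enum": ["protein", "chemical", "complex", "entity_set",
                   "gene", "rna", "process_node"]
        },
        "displayName": {"type": "string"},
        "bounds": {"$ref": "#/$defs/rect"},
        "compartmentId": {"type": "string"}
      }
    },
    "connector": {
      "type": "object",
      "required": ["role", "nodeId", "points"],
      "properties": {
        "role": {"enum": ["input", "output", "catalyst", "activator", "inhibitor"]},
        "nodeId": {"type": "string"},
        "points": {"type": "array", "items": {"$ref": "#/$defs/point"}, "minItems": 1},
        "ending": {"enum": ["none", "arrow", "circle", "bar"]}
      }
    },
    "edge": {
      "type": "object",
      "required": ["id", "reactionPoint", "segments", "connectors"],
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "reactionPoint": {"$ref": "#/$defs/point"},
        "segments": {"type": "array", "items": {"$ref": "#/$defs/point"}},
        "connectors": {"type": "array", "items": {"$ref": "#/$defs/connector"}}
      }
    },
    "compartment": {
      "type": "object",
      "required": ["id", "name", "outer"],
      "properties": {
        "id": {"type": "string", "minLength": 1},
        "name": {"type": "string"},
        "outer": {"$ref": "#/$defs/rect"},
        "inner": {"$ref": "#/$defs/rect"}
      }
    },
    "subpathways": {
      "type": "object",
      "required": ["parentPathwayId", "groups"],
      "properties": {
        "parentPathwayId": {"type": "string"},
        "groups": {
          "type": "object",
          "additionalProperties": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 1
          }
        },
        "displayNames": {
          "type": "object",
          "additionalProperties": {"type": "string"}
        }
      }
    }
  }
}
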