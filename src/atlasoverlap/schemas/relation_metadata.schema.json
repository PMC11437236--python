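{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SANDS-style atlas and region-relation metadata documents",
  "description": "Field names follow the openMINDS SANDS atlas schemas (BrainAtlas, BrainAtlasVersion, ParcellationTerminologyVersion, ParcellationEntityVersion, AtlasAnnotation, qualitativeRelationAssessment, quantitativeRelationAssessment). Documents are plain JSON; @context and versioned IRI minting are out of scope.",
  "type": "array",
  "items": {"type": "object", "required": ["@type", "@id"]},
  "$defs": {
    "reference": {
      "type": "object",
      "required": ["@id"],
      "properties": {"@id": {"type": "string"}},
      "additionalProperties": false
    },
    "qualitativeRelationAssessment": {
      "type": "object",
      "required": ["inRelationTo", "qualitativeOverlap"],
      "properties": {
        "inRelationTo": {"$ref": "#/$defs/reference"},
        "qualitativeOverlap": {
          "type": "string",
          "enum": ["isIdenticalTo", "isSubsetOf", "isSupersetOf", "hasIntersectionWith"]
        },
        "criteria": {"type": "string"}
      },
      "additionalProperties": false
    },
    "quantitativeRelationAssessment": {
      "type": "object",
      "required": ["inRelationTo", "quantitativeOverlap"],
      "properties": {
        "inRelationTo": {"$ref": "#/$defs/reference"},
        "quantitativeOverlap": {
          "type": "object",
          "required": ["value", "unit"],
          "properties": {
            "value": {"type": "number", "minimum": 0, "maximum": 100},
            "unit": {"type": "string", "enum": ["percent"]}
          },
          "additionalProperties": false
        },
        "criteria": {"type": "string"}
      },
      "additionalProperties": false
    },
    "AtlasAnnotation": {
      "type": "object",
      "required": ["@type", "internalIdentifier"],
      "properties": {
        "@type": {"type": "string", "enum": ["AtlasAnnotation"]},
        "internalIdentifier": {"type": "string"},
        "annotationFile": {"type": "string"}
      },
      "additionalProperties": false
    },
    "BrainAtlas": {
      "type": "object",
      "required": ["@type", "@id", "shortName", "hasVersion"],
      "properties": {
        "@type": {"type": "string", "enum": ["BrainAtlas"]},
        "@id": {"type": "string"},
        "shortName": {"type": "string"},
        "fullName": {"type": "string"},
        "hasVersion": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/reference"}}
      },
      "additionalProperties": false
    },
    "BrainAtlasVersion": {
      "type": "object",
      "required": ["@type", "@id", "shortName", "versionIdentifier", "hasTerminologyVersion"],
      "properties": {
        "@type": {"type": "string", "enum": ["BrainAtlasVersion"]},
        "@id": {"type": "string"},
        "shortName": {"type": "string"},
        "versionIdentifier": {"type": "string"},
        "publicationYear": {"type": ["integer", "null"]},
        "usedReferenceData": {"type": ["string", "null"]},
        "hasTerminologyVersion": {"$ref": "#/$defs/reference"}
      },
      "additionalProperties": false
    },
    "ParcellationTerminologyVersion": {
      "type": "object",
      "required": ["@type", "@id", "hasEntityVersion"],
      "properties": {
        "@type": {"type": "string", "enum": ["ParcellationTerminologyVersion"]},
        "@id": {"type": "string"},
        "hasEntityVersion": {"type": "array", "items": {"$ref": "#/$defs/reference"}}
      },
      "additionalProperties": false
    },
    "ParcellationEntityVersion": {
      "type": "object",
      "required": ["@type", "@id", "name", "abbreviation"],
      "properties": {
        "@type": {"type": "string", "enum": ["ParcellationEntityVersion"]},
        "@id": {"type": "string"},
        "name": {"type": "string"},
        "abbreviation": {"type": "string"},
        "versionInnovation": {"type": ["string", "null"]},
        "hasAnnotation": {"$ref": "#/$defs/AtlasAnnotation"},
        "qualitativeRelationAssessment": {
          "type": "array",
          "items": {"$ref": "#/$defs/qualitativeRelationAssessment"}
        },
        "quantitativeRelationAssessment": {
          "type": "array",
          "items": {"$ref": "#/$defs/quantitativeRelationAssessment"}
        }
      },
      "additionalProperties": false
    }
  }
}
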