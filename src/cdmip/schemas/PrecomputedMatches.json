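{
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "PrecomputedMatches",
    "type": "object",
    "required": ["inputImage", "results"],
    "properties": {
        "inputImage": {
            "type": "object",
            "required": ["id", "modality", "alignmentSpace", "libraryName", "publishedName", "files"],
            "properties": {
                "id": {"type": "string"},
                "modality": {"type": "string", "enum": ["EM", "LM"]},
                "alignmentSpace": {"type": "string"},
                "libraryName": {"type": "string"},
                "publishedName": {"type": "string"},
                "files": {"type": "object"}
            }
        },
        "algorithm": {"type": "string"},
        "results": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["image", "mirrored", "matchedPixels"],
                "properties": {
                    "image": {
                        "type": "object",
                        "required": ["id", "modality", "alignmentSpace", "libraryName", "publishedName", "files"],
                        "properties": {
                            "id": {"type": "string"},
                            "modality": {"type": "string", "enum": ["EM", "LM"]},
                            "alignmentSpace": {"type": "string"},
                            "libraryName": {"type": "string"},
                            "publishedName": {"type": "string"},
                            "files": {"type": "object"}
                        }
                    },
                    "mirrored": {"type": "boolean"},
                    "matchedPixels": {"type": "integer"},
                    "matchingShift": {"type": "array", "items": {"type": "integer"}},
                    "normalizedScore": {"type": "number"},
                    "shapePositive": {"type": "integer"},
                    "shapeNegative": {"type": "integer"},
                    "shapeScore": {"type": "number"}
                }
            }
        }
    }
}
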