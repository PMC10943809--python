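{
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "ImageLookup",
    "type": "object",
    "required": ["results"],
    "properties": {
        "results": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "modality", "alignmentSpace", "libraryName", "publishedName", "files"],
                "properties": {
                    "id": {"type": "string"},
                    "modality": {"type": "string", "enum": ["EM", "LM"]},
                    "alignmentSpace": {"type": "string"},
                    "libraryName": {"type": "string"},
                    "publishedName": {"type": "string"},
                    "variant": {"type": "string"},
                    "sampleId": {"type": "string"},
                    "files": {"type": "object"},
                    "attributes": {"type": "object"}
                }
            }
        }
    }
}
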