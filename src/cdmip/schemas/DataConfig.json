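{
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "DataConfig",
    "type": "object",
    "required": ["anatomicalAreas", "constants", "prefixes", "schemaVersion"],
    "properties": {
        "anatomicalAreas": {"type": "array", "items": {"type": "string"}},
        "constants": {"type": "object"},
        "prefixes": {"type": "object"},
        "schemaVersion": {"type": "string"}
    }
}
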