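{
  "type": "object",
  "required": ["parameters", "inputs", "stages", "timestamp"],
  "properties": {
    "parameters": {
      "type": "object",
      "required": ["threshold", "min_len", "boundary", "model", "consensus", "fdr", "seed"],
      "properties": {
        "threshold": {"type": "number"},
        "min_len": {"type": "integer"},
        "boundary": {"type": "string"},
        "model": {"type": "string"},
        "consensus": {"type": "string"},
        "fdr": {"type": "number"},
        "seed": {"type": "integer"}
      }
    },
    "inputs": {"type": "object"},
    "stages": {
      "type": "object",
      "properties": {
        "disorder": {
          "type": "object",
          "required": ["ch", "regions"],
          "properties": {
            "ch": {
              "type": "object",
              "required": ["h", "q", "label", "margin"],
              "properties": {
                "h": {"type": "number"},
                "q": {"type": "number"},
                "label": {"type": "string"},
                "margin": {"type": "number"}
              }
            },
            "regions": {"type": "array"}
          }
        },
        "hydro": {
          "type": "object",
          "required": ["apparent_mass_da", "r_apparent_A", "r_native_A", "increase_pct", "call"],
          "properties": {
            "apparent_mass_da": {"type": "number"},
            "r_apparent_A": {"type": "number"},
            "r_native_A": {"type": "number"},
            "increase_pct": {"type": "number"},
            "call": {"type": "string"}
          }
        },
        "evolution": {
          "type": "object",
          "required": ["reference", "regions"],
          "properties": {
            "reference": {"type": "string"},
            "regions": {"type": "object"}
          }
        },
        "phospho": {
          "type": "object",
          "required": ["n_sites", "positions"],
          "properties": {
            "n_sites": {"type": "integer"},
            "positions": {"type": "array"}
          }
        },
        "interactome": {
          "type": "object",
          "required": ["shell_sizes"],
          "properties": {
            "shell_sizes": {"type": "object"}
          }
        }
      }
    },
    "timestamp": {"type": "string"}
  }
}
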