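{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "lamdiff membrane metrics record",
  "type": "object",
  "required": ["label", "d_spacing_A", "n_orders", "method"],
  "properties": {
    "label": {"type": "string"},
    "temperature_C": {"type": "number"},
    "relative_humidity": {"type": "number"},
    "d2o_fraction": {"type": "number"},
    "d_spacing_A": {"type": "number"},
    "sigma_d_A": {"type": "number"},
    "method": {"type": "string"},
    "n_orders": {"type": "integer"},
    "d_b_A": {"type": "number"},
    "d_w_A": {"type": "number"},
    "trough_depth": {"type": "number"},
    "hump_amplitude": {"type": "number"},
    "hump_position_A": {"type": "number"},
    "signs": {"type": "array"},
    "flags": {"type": "array"},
    "error": {"type": "string"}
  }
}
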