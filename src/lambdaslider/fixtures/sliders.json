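[
  {"id": "standard", "a": 11.25, "bs": 70.0, "bt": 50.0, "xmin": -2.0, "xmax": 2.0},
  {"id": "shifted_positive", "a": 11.25, "bs": 90.0, "bt": 33.0, "xmin": -1.25, "xmax": 2.75},
  {"id": "shifted_negative", "a": 11.25, "bs": 90.0, "bt": 67.0, "xmin": -2.75, "xmax": 1.25},
  {"id": "balanced", "a": 7.0, "bs": 60.0, "bt": 45.0, "xmin": -2.0, "xmax": 2.0},
  {"id": "self_more", "a": 7.0, "bs": 95.0, "bt": 30.0, "xmin": -2.0, "xmax": 2.0},
  {"id": "target_more", "a": 7.0, "bs": 35.0, "bt": 70.0, "xmin": -2.0, "xmax": 2.0}
]
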