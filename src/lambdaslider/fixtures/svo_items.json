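{
  "note": "Endpoint payoffs of the six primary items of the published SVO Slider Measure (Murphy, Ackermann & Handgraaf). Each item is a linear slider from (ws0, wt0) at raw position 0 to (ws1, wt1) at raw position 1.",
  "items": [
    {"id": "item1", "ws0": 85, "wt0": 85, "ws1": 85, "wt1": 15},
    {"id": "item2", "ws0": 85, "wt0": 15, "ws1": 100, "wt1": 50},
    {"id": "item3", "ws0": 50, "wt0": 100, "ws1": 85, "wt1": 85},
    {"id": "item4", "ws0": 50, "wt0": 100, "ws1": 85, "wt1": 15},
    {"id": "item5", "ws0": 100, "wt0": 50, "ws1": 50, "wt1": 100},
    {"id": "item6", "ws0": 100, "wt0": 50, "ws1": 85, "wt1": 85}
  ]
}
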