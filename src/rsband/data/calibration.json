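{
  "conditions": {
    "grid_shape": [
      20,
      20,
      20
    ],
    "n_per_group": 16,
    "roi_radius_mm": 10.0,
    "band": "conventional",
    "seeds": [
      0,
      1
    ]
  },
  "alff": {
    "param": [
      0.0,
      0.3,
      0.5,
      0.7,
      0.9,
      1.2,
      1.6
    ],
    "d": [
      0.0,
      0.13688146408248497,
      0.4614457588319145,
      0.9009753377596623,
      1.417405874477969,
      2.2632454550266665,
      3.3895165605812028
    ]
  },
  "reho": {
    "param": [
      0.0,
      0.05,
      0.1,
      0.15,
      0.2,
      0.3,
      0.5
    ],
    "d": [
      0.0,
      0.1392056319149451,
      0.5662114606438133,
      1.1825055925948458,
      1.9269838372154062,
      3.683778304399352,
      8.161776585332392
    ]
  },
  "dc_hub": {
    "param": [
      0.0,
      0.03,
      0.06,
      0.1,
      0.15,
      0.25,
      0.4
    ],
    "d": [
      0.0,
      0.05193948474793147,
      0.4380327874128098,
      1.2747167478814465,
      2.520523134962067,
      4.482609631375518,
      6.436698597258696
    ]
  }
}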