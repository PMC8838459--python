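{
  "description": "Package-default error-grid partition of the (reference MAP, estimated MAP) plane, mmHg, over [0, 300] x [0, 300]. Regions are symmetric bands around the identity line of half-width b + a*reference: A (a=0.05, b=5), B (0.10, 12), C (0.15, 20), D (0.25, 35), E elsewhere. This is the package's own configurable default geometry; substitute your own file for a different clinical-risk convention.",
  "domain": [[0.0, 300.0], [0.0, 300.0]],
  "regions": {
    "A": [
      [[0.0, 0.0], [5.2632, 0.0], [300.0, 280.0], [300.0, 300.0], [280.9524, 300.0], [0.0, 5.0]]
    ],
    "B": [
      [[0.0, 5.0], [280.9524, 300.0], [261.8182, 300.0], [0.0, 12.0]],
      [[5.2632, 0.0], [13.3333, 0.0], [300.0, 258.0], [300.0, 280.0]]
    ],
    "C": [
      [[0.0, 12.0], [261.8182, 300.0], [243.4783, 300.0], [0.0, 20.0]],
      [[13.3333, 0.0], [23.5294, 0.0], [300.0, 235.0], [300.0, 258.0]]
    ],
    "D": [
      [[0.0, 20.0], [243.4783, 300.0], [212.0, 300.0], [0.0, 35.0]],
      [[23.5294, 0.0], [46.6667, 0.0], [300.0, 190.0], [300.0, 235.0]]
    ],
    "E": [
      [[0.0, 35.0], [212.0, 300.0], [0.0, 300.0]],
      [[46.6667, 0.0], [300.0, 0.0], [300.0, 190.0]]
    ]
  }
}
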