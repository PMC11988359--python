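{
  "gamma": 267515250.0,
  "sequences": [
    {
      "kind": "ogse_cos",
      "label": "ogse25",
      "f": 25.0,
      "n_cycles": 1,
      "delta": 40.0,
      "Delta": 52.0,
      "te": 105.0,
      "b_values": [0, 250, 500, 750, 1000],
      "nsa": [1, 1, 2, 3, 4]
    },
    {
      "kind": "ogse_cos",
      "label": "ogse50",
      "f": 50.0,
      "n_cycles": 2,
      "delta": 40.0,
      "Delta": 52.0,
      "te": 105.0,
      "b_values": [0, 100, 200, 250],
      "nsa": [1, 1, 1, 1]
    },
    {
      "kind": "pgse",
      "label": "pgse",
      "f": 0.0,
      "n_cycles": 0,
      "delta": 12.0,
      "Delta": 82.4,
      "te": 105.0,
      "b_values": [0, 250, 500, 750, 1000, 1400, 1800],
      "nsa": [1, 1, 2, 3, 4, 5, 6]
    }
  ]
}
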