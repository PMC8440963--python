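{
  "name": "10-20-22",
  "grid_height": 6,
  "grid_width": 7,
  "placement": {
    "Fz":  [0, 3],
    "FC3": [1, 1],
    "FC1": [1, 2],
    "FCz": [1, 3],
    "FC2": [1, 4],
    "FC4": [1, 5],
    "C5":  [2, 0],
    "C3":  [2, 1],
    "C1":  [2, 2],
    "Cz":  [2, 3],
    "C2":  [2, 4],
    "C4":  [2, 5],
    "C6":  [2, 6],
    "CP3": [3, 1],
    "CP1": [3, 2],
    "CPz": [3, 3],
    "CP2": [3, 4],
    "CP4": [3, 5],
    "P1":  [4, 2],
    "Pz":  [4, 3],
    "P2":  [4, 4],
    "POz": [5, 3]
  }
}
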