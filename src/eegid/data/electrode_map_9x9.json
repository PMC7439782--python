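{
  "description": "62-channel 10-20 extended montage on a 9x9 scalp grid; rows run front to back, columns left to right; null marks a grid cell with no electrode.",
  "grid": [
    [null, null, null, "FP1", "FPZ", "FP2", null, null, null],
    [null, null, null, "AF3", null, "AF4", null, null, null],
    ["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"],
    ["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"],
    ["T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"],
    ["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"],
    ["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"],
    [null, "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8", null],
    [null, null, "CB1", "O1", "OZ", "O2", "CB2", null, null]
  ]
}
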