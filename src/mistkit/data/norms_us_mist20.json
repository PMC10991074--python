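{
  "country": "US",
  "scale": "MIST-20",
  "n": 3479,
  "grids": {
    "V": {"0": 4, "5": 8, "10": 9, "15": 10, "20": 10, "25": 11, "30": 12, "35": 12, "40": 13, "45": 14, "50": 14, "55": 15, "60": 15, "65": 16, "70": 16, "75": 17, "80": 17, "85": 18, "90": 19, "95": 19, "100": 20},
    "f": {"0": 0, "5": 3, "10": 4, "15": 5, "20": 5, "25": 6, "30": 7, "35": 7, "40": 7, "45": 8, "50": 8, "55": 8, "60": 9, "65": 9, "70": 9, "75": 9, "80": 10, "85": 10, "90": 10, "95": 10, "100": 10},
    "r": {"0": 0, "5": 2, "10": 3, "15": 4, "20": 4, "25": 5, "30": 5, "35": 6, "40": 6, "45": 7, "50": 7, "55": 7, "60": 7, "65": 8, "70": 8, "75": 8, "80": 9, "85": 9, "90": 10, "95": 10, "100": 10}
  }
}
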