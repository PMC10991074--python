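{
  "dimension": "V",
  "tables": [
    {"scale": "MIST-8", "country": "US", "quartiles": {"min": 0, "q1": 4, "median": 6, "mean": 6, "q3": 7, "max": 8}},
    {"scale": "MIST-8", "country": "UK", "quartiles": {"min": 0, "q1": 4, "median": 5, "mean": 5, "q3": 7, "max": 8}},
    {"scale": "MIST-20", "country": "US", "quartiles": {"min": 4, "q1": 11, "median": 14, "mean": 14, "q3": 17, "max": 20}},
    {"scale": "MIST-20", "country": "UK", "quartiles": {"min": 4, "q1": 11, "median": 13, "mean": 13, "q3": 16, "max": 20}}
  ]
}
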