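{
  "name": "cldq-nash-default",
  "description": "Default item-to-domain assignment for the 36-item CLDQ-NASH. The assignment is a configuration of the scorer, sourced from the published instrument definition, and can be overridden with a JSON file of the same shape. Item numbers are 1-based positions in the cldq_01..cldq_36 columns.",
  "domains": {
    "abdominal": [1, 2, 3, 4, 5],
    "activity":  [6, 7, 8, 9, 10, 11, 12],
    "emotional": [13, 14, 15, 16, 17, 18, 19, 20],
    "fatigue":   [21, 22, 23, 24, 25, 26, 27],
    "systemic":  [28, 29, 30, 31],
    "worry":     [32, 33, 34, 35, 36]
  }
}
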