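{
  "description": "Published whole-dataset classification counts from a six-topic radiology abstract-screening evaluation: an ordinal 1-5 AI rater at four inclusion thresholds, three general-physician raters, and their three consensus rules, all tabulated against the expert-adjudicated gold standard.",
  "n_items": 1198,
  "n_positive": 148,
  "n_negative": 1050,
  "ai_rater": "ChatGPT",
  "ai_cumulative": {
    "2": {"tp": 141, "fp": 486},
    "3": {"tp": 140, "fp": 366},
    "4": {"tp": 107, "fp": 138},
    "5": {"tp": 15, "fp": 13}
  },
  "ai_operating_threshold": 3,
  "raters": {
    "GP 1": {"tp": 82, "tn": 990, "fp": 60, "fn": 66},
    "GP 2": {"tp": 81, "tn": 1037, "fp": 13, "fn": 67},
    "GP 3": {"tp": 109, "tn": 982, "fp": 68, "fn": 39},
    "Voting consensus": {"tp": 92, "tn": 1031, "fp": 19, "fn": 56},
    "Specific consensus": {"tp": 47, "tn": 1047, "fp": 3, "fn": 101},
    "Sensitive consensus": {"tp": 133, "tn": 931, "fp": 119, "fn": 15}
  }
}
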