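{
  "_comment": "Summary statistics as printed in the validation study's results table, used only for cross-checking reconstructions (never as computation inputs). Percentages on the 0-100 scale.",
  "LCAT": {
    "cronbach_alpha": 0.95,
    "cohen_kappa": 0.73,
    "weighted_kappa": 0.82,
    "exact_agreement_pct": 80.7,
    "extreme_disagreement_pct": 0.0
  },
  "LAAT": {
    "cronbach_alpha": 0.85,
    "cohen_kappa": 0.65,
    "weighted_kappa": 0.68,
    "exact_agreement_pct": 76.9,
    "extreme_disagreement_pct": 3.8
  }
}
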