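{
  "_comment": "Published one-vs-rest 2x2 agreement counts per category (n = 26 cases; rows = rater 2, columns = rater 1). both_yes/both_no agree on presence/absence of the category; rater2_only / rater1_only are the discordant cells. LAAT has no printed 2x2 for 'unassessable'; its rater-2 marginals sum to 23 of 26, read as three rater-2 'unassessable' ratings absent from the printed tables.",
  "n": 26,
  "LCAT": {
    "definite": {"both_yes": 5, "rater2_only": 0, "rater1_only": 1, "both_no": 20},
    "probable": {"both_yes": 6, "rater2_only": 4, "rater1_only": 0, "both_no": 16},
    "possible": {"both_yes": 7, "rater2_only": 1, "rater1_only": 3, "both_no": 15},
    "unlikely": {"both_yes": 3, "rater2_only": 0, "rater1_only": 1, "both_no": 22}
  },
  "LAAT": {
    "definitely_avoidable": {"both_yes": 6, "rater2_only": 0, "rater1_only": 4, "both_no": 16},
    "possibly_avoidable": {"both_yes": 8, "rater2_only": 1, "rater1_only": 1, "both_no": 16},
    "not_avoidable": {"both_yes": 6, "rater2_only": 2, "rater1_only": 1, "both_no": 17}
  }
}
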