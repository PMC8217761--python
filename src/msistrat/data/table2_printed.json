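{
  "description": "Published strategy-by-metric results table (dollar cells in billions USD). Cells listed under 'irreproducible' are documented as internally inconsistent with the published inputs under any coherent sequential-testing convention; the engine reports its computed values and the delta for those cells rather than matching them.",
  "metrics": {
    "total": {"A": 3.13, "B": 3.05, "C": 2.76, "D": 2.75, "E": 3.03, "F": 3.12, "G": 3.00, "H": 2.72},
    "chemotherapy": {"A": 2.12, "B": 1.70, "C": 1.97, "D": 2.08, "E": 2.12, "F": 2.07, "G": 1.70, "H": 1.97},
    "immunotherapy": {"A": 0.90, "B": 1.31, "C": 0.76, "D": 0.67, "E": 0.88, "F": 0.94, "G": 1.29, "H": 0.74},
    "testing": {"A": 0.11, "B": 0.04, "C": 0.04, "D": 0.00, "E": 0.03, "F": 0.11, "G": 0.02, "H": 0.01},
    "ttt_days": {"A": 12, "B": 4, "C": 4, "D": 0, "E": 3.0, "F": 11.4, "G": 1.6, "H": 1.2},
    "pct_within_guideline": {"A": 0, "B": 100, "C": 100, "D": 100, "E": 75, "F": 5, "G": 100, "H": 100},
    "pct_supported": {"A": 100, "B": 81, "C": 91, "D": 97, "E": 80, "F": 97, "G": 81, "H": 91}
  },
  "savings_abs_busd": {"B": 0.07, "C": 0.36, "D": 0.37, "E": 0.10, "F": 0.01, "G": 0.12, "H": 0.40},
  "savings_rel_pct": {"B": 2.3, "C": 11.6, "D": 11.9, "E": 3.2, "F": 0.2, "G": 3.9, "H": 12.9},
  "irreproducible": [
    ["B", "chemotherapy"], ["B", "immunotherapy"], ["B", "total"], ["B", "pct_supported"],
    ["C", "total"], ["C", "pct_supported"],
    ["D", "immunotherapy"], ["D", "total"],
    ["E", "immunotherapy"], ["E", "total"], ["E", "pct_supported"],
    ["F", "chemotherapy"], ["F", "immunotherapy"], ["F", "total"], ["F", "pct_supported"],
    ["G", "testing"], ["G", "chemotherapy"], ["G", "immunotherapy"], ["G", "total"], ["G", "ttt_days"], ["G", "pct_supported"],
    ["H", "chemotherapy"], ["H", "immunotherapy"], ["H", "total"], ["H", "ttt_days"], ["H", "pct_supported"]
  ]
}
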