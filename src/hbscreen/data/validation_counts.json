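{
  "comment": "Published clinical-validation confusion counts (screening call vs NGS-confirmed genotype, n=363 adjudicated newborns) and per-genotype detection counts for the targeted-MS screen and the capillary-electrophoresis (Sebia-CE) comparator.",
  "confusion": {
    "alpha_thalassemia": {
      "hplc_hrms": {"tp": 44, "fp": 60, "fn": 20, "tn": 239},
      "sebia_ce": {"tp": 44, "fp": 40, "fn": 20, "tn": 259}
    },
    "beta_thalassemia": {
      "hplc_hrms": {"tp": 39, "fp": 31, "fn": 1, "tn": 268},
      "sebia_ce": {"tp": 16, "fp": 33, "fn": 24, "tn": 266}
    },
    "alpha_and_beta_thalassemia": {
      "hplc_hrms": {"tp": 2, "fp": 0, "fn": 0, "tn": 299},
      "sebia_ce": {"tp": 0, "fp": 0, "fn": 2, "tn": 299}
    },
    "abnormal_hb": {
      "hplc_hrms": {"tp": 2, "fp": 0, "fn": 0, "tn": 299},
      "sebia_ce": {"tp": 2, "fp": 3, "fn": 0, "tn": 296}
    }
  },
  "per_genotype_detection": {
    "alpha_thalassemia_total": {"total": 64, "hplc_hrms": 44, "sebia_ce": 44},
    "aa/--SEA": {"total": 27, "hplc_hrms": 27, "sebia_ce": 20},
    "aa/-a3.7": {"total": 19, "hplc_hrms": 7, "sebia_ce": 14},
    "aa/-a4.2": {"total": 3, "hplc_hrms": 2, "sebia_ce": 2},
    "aa/aWSa": {"total": 1, "hplc_hrms": 1, "sebia_ce": 0},
    "aa/aCSa": {"total": 5, "hplc_hrms": 1, "sebia_ce": 4},
    "-a3.7/-a3.7": {"total": 2, "hplc_hrms": 0, "sebia_ce": 2},
    "aaa_anti3.7/aa": {"total": 2, "hplc_hrms": 2, "sebia_ce": 0},
    "aaa_anti4.2/aa": {"total": 4, "hplc_hrms": 3, "sebia_ce": 2},
    "aaa_anti3.7/--SEA": {"total": 1, "hplc_hrms": 1, "sebia_ce": 0},
    "beta_thalassemia_total": {"total": 40, "hplc_hrms": 39, "sebia_ce": 16},
    "bN/bCodon17": {"total": 13, "hplc_hrms": 13, "sebia_ce": 5},
    "bN/bIVS-II-654": {"total": 13, "hplc_hrms": 13, "sebia_ce": 5},
    "bN/bCodons41-42": {"total": 11, "hplc_hrms": 10, "sebia_ce": 6},
    "bN/bCodons27-28": {"total": 1, "hplc_hrms": 1, "sebia_ce": 0},
    "bN/bCodons71-72": {"total": 1, "hplc_hrms": 1, "sebia_ce": 0},
    "Chinese_Gg+(Agdb)0": {"total": 1, "hplc_hrms": 1, "sebia_ce": 0},
    "alpha_and_beta_total": {"total": 2, "hplc_hrms": 2, "sebia_ce": 0},
    "abnormal_hb_total": {"total": 2, "hplc_hrms": 2, "sebia_ce": 2},
    "Hb D-Los Angeles": {"total": 2, "hplc_hrms": 2, "sebia_ce": 2}
  }
}
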