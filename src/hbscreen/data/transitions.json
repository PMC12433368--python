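[
  {"peptide_id": "alphaT1", "sequence": "VLSPADK", "precursor_mz": 729.4141, "product_mz": 430.2296, "retention_time": 1.22, "collision_energy": 40, "is_internal_standard": false, "chain": "alpha"},
  {"peptide_id": "alphaT1", "sequence": "VLSPADK", "precursor_mz": 737.4280, "product_mz": 438.2430, "retention_time": 1.22, "collision_energy": 40, "is_internal_standard": true, "chain": "alpha"},
  {"peptide_id": "alphaT3", "sequence": "AAWGK", "precursor_mz": 532.2878, "product_mz": 461.2507, "retention_time": 1.11, "collision_energy": 36, "is_internal_standard": false, "chain": "alpha"},
  {"peptide_id": "alphaT3", "sequence": "AAWGK", "precursor_mz": 540.2800, "product_mz": 469.2647, "retention_time": 1.11, "collision_energy": 36, "is_internal_standard": true, "chain": "alpha"},
  {"peptide_id": "betaT1", "sequence": "VHLTPEEK", "precursor_mz": 476.7585, "product_mz": 716.3812, "retention_time": 1.34, "collision_energy": 20, "is_internal_standard": false, "chain": "beta"},
  {"peptide_id": "betaT1", "sequence": "VHLTPEEK", "precursor_mz": 480.7660, "product_mz": 724.3958, "retention_time": 1.34, "collision_energy": 16, "is_internal_standard": true, "chain": "beta"},
  {"peptide_id": "betaT2", "sequence": "SAVTALWGK", "precursor_mz": 466.7636, "product_mz": 675.3824, "retention_time": 1.67, "collision_energy": 18, "is_internal_standard": false, "chain": "beta"},
  {"peptide_id": "betaT2", "sequence": "SAVTALWGK", "precursor_mz": 470.7710, "product_mz": 68.3927, "retention_time": 1.67, "collision_energy": 16, "is_internal_standard": true, "chain": "beta", "note": "product m/z stored as published; 68.3927 Th is almost certainly a typographical error (expected ~683.9 or a y-ion near 684)"},
  {"peptide_id": "gammaT10", "sequence": "HLDDLK", "precursor_mz": 370.7005, "product_mz": 603.3348, "retention_time": 1.18, "collision_energy": 14, "is_internal_standard": false, "chain": "gamma"},
  {"peptide_id": "gammaT10", "sequence": "HLDDLK", "precursor_mz": 374.7080, "product_mz": 611.3493, "retention_time": 1.18, "collision_energy": 15, "is_internal_standard": true, "chain": "gamma"},
  {"peptide_id": "deltaT2", "sequence": "TAVNALWGK", "precursor_mz": 480.2691, "product_mz": 787.4461, "retention_time": 1.64, "collision_energy": 16, "is_internal_standard": false, "chain": "delta"},
  {"peptide_id": "deltaT2", "sequence": "TAVNALWGK", "precursor_mz": 484.2700, "product_mz": 795.4580, "retention_time": 1.64, "collision_energy": 16, "is_internal_standard": true, "chain": "delta"},
  {"peptide_id": "zetaT8", "sequence": "VVAAVGDAVK", "precursor_mz": 464.7767, "product_mz": 730.4094, "retention_time": 1.50, "collision_energy": 14, "is_internal_standard": false, "chain": "zeta"},
  {"peptide_id": "zetaT8", "sequence": "VVAAVGDAVK", "precursor_mz": 468.7840, "product_mz": 738.4230, "retention_time": 1.50, "collision_energy": 14, "is_internal_standard": true, "chain": "zeta"},
  {"peptide_id": "betaHbS_T1", "sequence": "VHLTPVEK", "precursor_mz": 461.7715, "product_mz": 412.2373, "retention_time": 1.41, "collision_energy": 20, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb S", "wildtype_partner": "betaT1"},
  {"peptide_id": "betaHbE_T3", "sequence": "VNVDEVGGK", "precursor_mz": 458.7404, "product_mz": 703.3621, "retention_time": 1.39, "collision_energy": 18, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb E"},
  {"peptide_id": "betaHbD_T13", "sequence": "QFTPPVQAAYQK", "precursor_mz": 689.3617, "product_mz": 1001.5415, "retention_time": 1.55, "collision_energy": 14, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb D-Los Angeles"},
  {"peptide_id": "betaHbG_T3", "sequence": "VNVDAVGGEALGR", "precursor_mz": 628.8333, "product_mz": 659.3471, "retention_time": 1.53, "collision_energy": 20, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb G-Coushatta"},
  {"peptide_id": "betaHbWatford_T1", "sequence": "GHLTPEEK", "precursor_mz": 455.7351, "product_mz": 502.2508, "retention_time": 0.90, "collision_energy": 20, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb Watford", "wildtype_partner": "betaT1"},
  {"peptide_id": "alphaHbNanchang_T3", "sequence": "AAWSK", "precursor_mz": 562.2984, "product_mz": 420.2242, "retention_time": 1.04, "collision_energy": 17, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb Nanchang"},
  {"peptide_id": "alphaHbHekinan_T4", "sequence": "VGAHAGEYGADALER", "precursor_mz": 758.3630, "product_mz": 1080.4956, "retention_time": 1.43, "collision_energy": 37, "is_internal_standard": false, "chain": "variant", "variant_name": "Hb Hekinan II"}
]
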