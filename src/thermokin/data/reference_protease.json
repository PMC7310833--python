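{
  "description": "Published reference characterization of a recombinant 18 kDa thermostable cysteine protease (activity optimum 60 degC, pH 7; casein substrate). Printed table values used by the reproduce harness; cells known to be internally inconsistent are listed under flagged_cells.",
  "molecular_weight_g_mol": 18000,
  "optimum_temperature_C": 60,
  "optimum_pH": 7,
  "kinetics": {
    "Km_mM": 13.72,
    "Vmax_U_mg": 2.657,
    "kcat_per_s": 0.003143,
    "efficiency_per_M_s": 0.381,
    "Ea_kJ_mol": 35.04,
    "dG_kJ_mol": 74.36,
    "dH_kJ_mol": 32.68,
    "dS_magnitude_J_mol_K": 125,
    "dG_ET_kJ_mol": -2.66,
    "dG_ES_kJ_mol": 0.19,
    "Ka_per_mM": 0.07
  },
  "inactivation": {
    "Ea_kJ_mol": 50.31,
    "rows": [
      {"temperature_C": 60, "kin_per_min": 0.0021, "t_half_min": 330.07, "d_value_min": 1318.52, "dH_kJ_mol": 47.54, "dG_kJ_mol": 98.71, "dS_magnitude_J_mol_K": 154.70},
      {"temperature_C": 70, "kin_per_min": 0.0087, "t_half_min": 79.67, "d_value_min": 327.82, "dH_kJ_mol": 47.54, "dG_kJ_mol": 97.83, "dS_magnitude_J_mol_K": 147.60},
      {"temperature_C": 80, "kin_per_min": 0.0104, "t_half_min": 66.65, "d_value_min": 282.23, "dH_kJ_mol": 47.37, "dG_kJ_mol": 100.27, "dS_magnitude_J_mol_K": 149.85},
      {"temperature_C": 90, "kin_per_min": 0.0171, "t_half_min": 40.53, "d_value_min": 176.51, "dH_kJ_mol": 47.28, "dG_kJ_mol": 101.56, "dS_magnitude_J_mol_K": 149.51},
      {"temperature_C": 100, "kin_per_min": 0.0312, "t_half_min": 22.27, "d_value_min": 99.40, "dH_kJ_mol": 47.20, "dG_kJ_mol": 102.52, "dS_magnitude_J_mol_K": 148.29}
    ]
  },
  "purification": [
    {"step": "Crude extract", "volume_ml": 50, "total_activity_U": 14.1, "total_protein_mg": 49.2, "specific_activity_U_mg": 0.28, "yield_percent": 100, "fold": 1},
    {"step": "Ni-NTA", "volume_ml": 4, "total_activity_U": 12.4, "total_protein_mg": 0.7, "specific_activity_U_mg": 17.7, "yield_percent": 87.9, "fold": 62.3},
    {"step": "Thermal shock", "volume_ml": 4, "total_activity_U": 10.3, "total_protein_mg": 0.8, "specific_activity_U_mg": 12.9, "yield_percent": 73.1, "fold": 45.4}
  ],
  "substrate_specificity": {"casein": 100, "gelatin": 90, "azo-casein": 25, "BSA": 10},
  "effectors": [
    {"name": "beta-mercaptoethanol", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [150.6, 2.3], "2": [143.3, 2.1], "3": [126.9, 15.4]}},
    {"name": "methanol", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [120.0, 1.8], "2": [113.6, 2.4], "3": [83.9, 7.8]}},
    {"name": "ethanol", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [99.1, 7.7], "2": [98.4, 2.6], "3": [86.9, 3.4]}},
    {"name": "isopropanol", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [94.8, 5.0], "2": [93.6, 4.1], "3": [86.6, 5.5]}},
    {"name": "glycerol", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [126.9, 3.8], "2": [117.8, 2.7], "3": [94.4, 2.3]}},
    {"name": "acetone", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [92.1, 5.2], "2": [93.9, 3.8], "3": [90.6, 1.4]}},
    {"name": "DMSO", "class": "organic_solvent", "unit": "% v/v", "values": {"1": [116.9, 2.3], "2": [122.1, 3.2], "3": [86.6, 3.4]}},
    {"name": "GuHCl", "class": "inhibitor", "unit": "% v/v", "values": {"1": [91.8, 2.7], "2": [82.1, 1.3]}},
    {"name": "DTT", "class": "inhibitor", "unit": "% v/v", "values": {"1": [95.7, 3.4], "2": [87.2, 3.9]}},
    {"name": "PMSF", "class": "inhibitor", "unit": "% v/v", "values": {"1": [79.3, 3.4], "2": [48.4, 1.3]}},
    {"name": "IAA", "class": "inhibitor", "unit": "% v/v", "values": {"1": [10.2, 1.4]}},
    {"name": "EDTA", "class": "inhibitor", "unit": "% v/v", "values": {"1": [97.8, 2.2], "2": [94.8, 3.6]}},
    {"name": "Tween 20", "class": "surfactant", "unit": "% v/v", "values": {"1": [415.7, 5.0], "2": [350.3, 5.0]}},
    {"name": "Tween 80", "class": "surfactant", "unit": "% v/v", "values": {"1": [488.7, 7.8], "2": [460.0, 19.5]}},
    {"name": "SDS", "class": "surfactant", "unit": "% v/v", "values": {"1": [100.0, 1.7], "2": [59.0, 0.9]}}
  ],
  "flagged_cells": [
    "kcat_per_s: printed value not derivable from Vmax and molecular weight under the package's unit convention",
    "efficiency_per_M_s: printed value inconsistent with printed kcat/Km (0.003143/0.01372 ~ 0.229)",
    "dG_ES_kJ_mol: printed 0.19 not reproducible from Km = 13.72 mM under any unit convention",
    "kinetics Ea_kJ_mol: underlying per-temperature rates not printed; taken as input",
    "inactivation Ea_kJ_mol: printed 50.31 inconsistent with an Arrhenius fit of the printed kin column (~63.1); taken as input",
    "t_half at 100 degC: printed 22.27 vs ln2/kin = 22.22",
    "dH at 70 degC: printed 47.54 vs Ea - RT = 47.46 (duplicate of the 60 degC cell)",
    "purification folds: printed 62.3/45.4 vs full-precision 61.8/44.9",
    "crude extract specific activity: printed 0.28 vs 14.1/49.2 = 0.287 (rounds to 0.29)",
    "thermal shock yield: printed 73.1 vs 100*10.3/14.1 = 73.05 (rounds to 73.0)"
  ]
}
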