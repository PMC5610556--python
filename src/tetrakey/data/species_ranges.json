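{
  "jarawa": {
    "group": "inglebyi",
    "n": 2,
    "type_locality": {"latitude": 11.975817, "longitude": 93.016897, "elevation_m": 5},
    "measurements_mm": {
      "HL": [0.56, 0.59, 0.56],
      "HW": [0.52, 0.54, 0.52],
      "SL": [0.32, 0.38, 0.32],
      "EL": [0.05, 0.05, 0.05],
      "PH": [0.27, 0.28, 0.27],
      "PW": [0.35, 0.37, 0.35],
      "WL": [0.62, 0.65, 0.62],
      "PSL": [0.10, 0.10, 0.10],
      "PTL": [0.14, 0.16, 0.14],
      "PTH": [0.17, 0.19, 0.17],
      "PTW": [0.16, 0.17, 0.16],
      "PPL": [0.17, 0.17, 0.17],
      "PPH": [0.18, 0.19, 0.18],
      "PPW": [0.20, 0.22, 0.20]
    },
    "indices_printed": {
      "CI": [92, 94, 94],
      "SI": [60, 71, 60],
      "OI": [9, 10, 10],
      "DMI": [56, 56, 56],
      "LMI": [43, 44, 44],
      "PSLI": [18, 18, 18],
      "PeNI": [45, 45, 45],
      "LPeI": [81, 83, 81],
      "DPeI": [105, 112, 112],
      "PpNI": [57, 59, 57],
      "LPpI": [87, 91, 91],
      "DPpI": [120, 130, 120],
      "PPI": [126, 130, 126]
    },
    "notes": [
      "Documented discrepancy: the description text gives LPpI 86-87 while the measurement list gives LPpI 87-91 (91); the packaged range records the measurement-list values.",
      "Documented discrepancy: the description text gives PPI 126-127 while the measurement list gives PPI 126-130 (126); the packaged range records the measurement-list values.",
      "DPeI is known to misrepresent nodes whose dorsum is narrower than the base; the published DPeI 105-112 suggests a node weakly broader than long although the node dorsum is much longer than broad. No alternative measurement is defined, so none is encoded."
    ]
  },
  "krishnani": {
    "group": "tonganum",
    "n": 6,
    "type_locality": {"latitude": 12.003499, "longitude": 92.993196, "elevation_m": 93},
    "measurements_mm": {
      "HL": [0.58, 0.64, 0.61],
      "HW": [0.51, 0.57, 0.54],
      "SL": [0.40, 0.46, 0.43],
      "EL": [0.12, 0.14, 0.14],
      "PH": [0.28, 0.33, 0.28],
      "PW": [0.37, 0.42, 0.40],
      "WL": [0.67, 0.78, 0.74],
      "PSL": [0.02, 0.02, 0.02],
      "PTL": [0.22, 0.26, 0.22],
      "PTH": [0.19, 0.22, 0.20],
      "PTW": [0.18, 0.20, 0.19],
      "PPL": [0.22, 0.25, 0.25],
      "PPH": [0.17, 0.19, 0.17],
      "PPW": [0.18, 0.20, 0.20]
    },
    "indices_printed": {
      "CI": [86, 88, 88],
      "SI": [79, 81, 80],
      "OI": [25, 26, 26],
      "DMI": [52, 56, 54],
      "LMI": [38, 45, 38],
      "PSLI": [3.1, 3.4, 3.2],
      "PeNI": [46, 51, 47],
      "LPeI": [112, 119, 112],
      "DPeI": [76, 85, 84],
      "PpNI": [47, 54, 49],
      "LPpI": [118, 143, 143],
      "DPpI": [78, 89, 78],
      "PPI": [100, 104, 103]
    },
    "notes": []
  }
}
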