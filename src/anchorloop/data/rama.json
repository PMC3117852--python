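{
  "version": 1,
  "comment": "Compact parametric backbone-torsion model: Gaussian basins per residue class. Angles in degrees; weights sum to 1 within a class. Basin membership is defined as lying within trunc_sigma standard deviations of a basin center.",
  "trunc_sigma": 2.5,
  "classes": {
    "general": [
      {"phi": -63.0, "psi": -43.0, "sigma_phi": 14.0, "sigma_psi": 16.0, "weight": 0.42},
      {"phi": -118.0, "psi": 134.0, "sigma_phi": 24.0, "sigma_psi": 22.0, "weight": 0.46},
      {"phi": 61.0, "psi": 42.0, "sigma_phi": 12.0, "sigma_psi": 14.0, "weight": 0.12}
    ],
    "glycine": [
      {"phi": -63.0, "psi": -40.0, "sigma_phi": 16.0, "sigma_psi": 18.0, "weight": 0.3},
      {"phi": 63.0, "psi": 40.0, "sigma_phi": 16.0, "sigma_psi": 18.0, "weight": 0.3},
      {"phi": -90.0, "psi": 150.0, "sigma_phi": 25.0, "sigma_psi": 25.0, "weight": 0.2},
      {"phi": 90.0, "psi": -150.0, "sigma_phi": 25.0, "sigma_psi": 25.0, "weight": 0.2}
    ],
    "proline": [
      {"phi": -63.0, "psi": -33.0, "sigma_phi": 9.0, "sigma_psi": 12.0, "weight": 0.4},
      {"phi": -63.0, "psi": 147.0, "sigma_phi": 9.0, "sigma_psi": 14.0, "weight": 0.6}
    ]
  }
}
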