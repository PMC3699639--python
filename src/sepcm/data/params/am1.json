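{
  "method": "AM1",
  "source": "Dewar, Zoebisch, Healy & Stewart (1985) AM1 parameterization for H, C, N, O as distributed with public-domain MOPAC parameter tables",
  "units": {
    "uss": "eV", "upp": "eV", "zs": "bohr^-1", "zp": "bohr^-1",
    "betas": "eV", "betap": "eV", "alpha": "angstrom^-1",
    "gss": "eV", "gsp": "eV", "gpp": "eV", "gp2": "eV", "hsp": "eV",
    "gaussians": "[K (eV), L (angstrom^-2), M (angstrom)]",
    "eisol": "eV", "eheat": "kcal/mol"
  },
  "elements": {
    "H": {
      "z": 1, "zval": 1, "nq": 1,
      "uss": -11.396427, "upp": 0.0,
      "zs": 1.188078, "zp": 0.0,
      "betas": -6.173787, "betap": 0.0,
      "alpha": 2.882324,
      "gss": 12.848, "gsp": 0.0, "gpp": 0.0, "gp2": 0.0, "hsp": 0.0,
      "gaussians": [[0.122796, 5.0, 1.2], [0.005090, 5.0, 1.8], [-0.018336, 2.0, 2.1]],
      "eisol": -11.396427, "eheat": 52.102
    },
    "C": {
      "z": 6, "zval": 4, "nq": 2,
      "uss": -52.028658, "upp": -39.614239,
      "zs": 1.808665, "zp": 1.685116,
      "betas": -15.715783, "betap": -7.719283,
      "alpha": 2.648274,
      "gss": 12.23, "gsp": 11.47, "gpp": 11.08, "gp2": 9.84, "hsp": 2.43,
      "gaussians": [[0.011355, 5.0, 1.6], [0.045924, 5.0, 1.85], [-0.020061, 5.0, 2.05], [-0.001260, 5.0, 2.65]],
      "eisol": -120.814975, "eheat": 170.89
    },
    "N": {
      "z": 7, "zval": 5, "nq": 2,
      "uss": -71.86, "upp": -57.167581,
      "zs": 2.315410, "zp": 2.157940,
      "betas": -20.299110, "betap": -18.238666,
      "alpha": 2.947286,
      "gss": 13.59, "gsp": 12.66, "gpp": 12.98, "gp2": 11.59, "hsp": 3.14,
      "gaussians": [[0.025251, 5.0, 1.5], [0.028953, 5.0, 2.1], [-0.005806, 2.0, 2.4]],
      "eisol": -202.409413, "eheat": 113.0
    },
    "O": {
      "z": 8, "zval": 6, "nq": 2,
      "uss": -97.83, "upp": -78.262380,
      "zs": 3.108032, "zp": 2.524039,
      "betas": -29.272773, "betap": -29.272773,
      "alpha": 4.455371,
      "gss": 15.42, "gsp": 14.48, "gpp": 14.52, "gp2": 12.98, "hsp": 3.94,
      "gaussians": [[0.280962, 5.0, 0.847918], [0.081430, 7.0, 1.445071]],
      "eisol": -316.099520, "eheat": 59.559
    }
  }
}
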