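{
  "method": "MNDO",
  "source": "Dewar & Thiel (1977) MNDO parameterization for H, C, N, O as distributed with public-domain MOPAC parameter tables",
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
      "uss": -11.906276, "upp": 0.0,
      "zs": 1.331967, "zp": 0.0,
      "betas": -6.989064, "betap": 0.0,
      "alpha": 2.544134,
      "gss": 12.848, "gsp": 0.0, "gpp": 0.0, "gp2": 0.0, "hsp": 0.0,
      "gaussians": [],
      "eisol": -11.906276, "eheat": 52.102
    },
    "C": {
      "z": 6, "zval": 4, "nq": 2,
      "uss": -52.279745, "upp": -39.205558,
      "zs": 1.787537, "zp": 1.787537,
      "betas": -18.985044, "betap": -7.934122,
      "alpha": 2.546380,
      "gss": 12.23, "gsp": 11.47, "gpp": 11.08, "gp2": 9.84, "hsp": 2.43,
      "gaussians": [],
      "eisol": -120.500606, "eheat": 170.89
    },
    "N": {
      "z": 7, "zval": 5, "nq": 2,
      "uss": -71.932122, "upp": -57.172319,
      "zs": 2.255614, "zp": 2.255614,
      "betas": -20.495758, "betap": -20.495758,
      "alpha": 2.861342,
      "gss": 13.59, "gsp": 12.66, "gpp": 12.98, "gp2": 11.59, "hsp": 3.14,
      "gaussians": [],
      "eisol": -202.566201, "eheat": 113.0
    },
    "O": {
      "z": 8, "zval": 6, "nq": 2,
      "uss": -99.644309, "upp": -77.797472,
      "zs": 2.699905, "zp": 2.699905,
      "betas": -32.688082, "betap": -32.688082,
      "alpha": 3.160604,
      "gss": 15.42, "gsp": 14.48, "gpp": 14.52, "gp2": 12.98, "hsp": 3.94,
      "gaussians": [],
      "eisol": -317.868506, "eheat": 59.559
    }
  }
}
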