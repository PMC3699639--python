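{
  "method": "PM3",
  "source": "Stewart (1989) PM3 parameterization for H, C, N, O as distributed with public-domain MOPAC parameter tables",
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
      "uss": -13.073321, "upp": 0.0,
      "zs": 0.967807, "zp": 0.0,
      "betas": -5.626512, "betap": 0.0,
      "alpha": 3.356386,
      "gss": 14.794208, "gsp": 0.0, "gpp": 0.0, "gp2": 0.0, "hsp": 0.0,
      "gaussians": [[1.128750, 5.096282, 1.537465], [-1.060329, 6.003788, 1.570189]],
      "eisol": -13.073321, "eheat": 52.102
    },
    "C": {
      "z": 6, "zval": 4, "nq": 2,
      "uss": -47.270320, "upp": -36.266918,
      "zs": 1.565085, "zp": 1.842345,
      "betas": -11.910015, "betap": -9.802755,
      "alpha": 2.707807,
      "gss": 11.200708, "gsp": 10.265027, "gpp": 10.796292, "gp2": 9.042566, "hsp": 2.290980,
      "gaussians": [[0.050107, 6.003165, 1.642214], [0.050733, 6.002979, 0.892488]],
      "eisol": -111.229917, "eheat": 170.89
    },
    "N": {
      "z": 7, "zval": 5, "nq": 2,
      "uss": -49.335672, "upp": -47.509736,
      "zs": 2.028094, "zp": 2.313728,
      "betas": -14.062521, "betap": -20.043848,
      "alpha": 2.830545,
      "gss": 11.904787, "gsp": 7.348565, "gpp": 11.754672, "gp2": 10.807277, "hsp": 1.136713,
      "gaussians": [[1.501674, 5.901148, 1.710740], [-1.505772, 6.004658, 1.716149]],
      "eisol": -157.6137755, "eheat": 113.0
    },
    "O": {
      "z": 8, "zval": 6, "nq": 2,
      "uss": -86.993002, "upp": -71.879580,
      "zs": 3.796544, "zp": 2.389402,
      "betas": -45.202651, "betap": -24.752515,
      "alpha": 3.217102,
      "gss": 15.755760, "gsp": 10.621160, "gpp": 13.654016, "gp2": 12.406095, "hsp": 0.593883,
      "gaussians": [[-1.131128, 6.002477, 1.607311], [1.137891, 5.950512, 1.598395]],
      "eisol": -289.3422065, "eheat": 59.559
    }
  }
}
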