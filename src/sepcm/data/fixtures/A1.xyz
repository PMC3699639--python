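5
A1 [NH4+] charge=1 provenance=RDKit-ETKDG+MMFF94
N     -0.00000011     0.00000000     0.00000002
H     -0.47698966    -0.72769322    -0.54514138
H     -0.55154407     0.21619373     0.83862678
H      0.09894406     0.84674661    -0.57224630
H      0.92958979    -0.33524713     0.27876088
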