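{
  "_comment": "Bond-valence R0 parameters (A) per metal element / donor element pair, b = 0.37 A; standard published values for the common oxidation states of the metals handled by the pipeline.",
  "FE": {"O": 1.759, "N": 1.815, "S": 2.12},
  "CU": {"O": 1.679, "N": 1.713, "S": 2.054},
  "ZN": {"O": 1.704, "N": 1.77, "S": 2.09},
  "MN": {"O": 1.79, "N": 1.849, "S": 2.22},
  "MG": {"O": 1.693, "N": 1.85, "S": 2.18},
  "MO": {"O": 1.907, "N": 2.043, "S": 2.331},
  "NI": {"O": 1.654, "N": 1.7, "S": 2.04},
  "CO": {"O": 1.692, "N": 1.84, "S": 2.06}
}
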