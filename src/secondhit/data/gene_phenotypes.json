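{
  "USH2A": {"inheritance": "recessive", "phenotypes": ["arRP", "sRP", "RP", "USH"]},
  "ABCA4": {"inheritance": "recessive", "phenotypes": ["STGD", "COD", "arRP", "sRP", "RP"]},
  "CEP290": {"inheritance": "recessive", "phenotypes": ["LCA", "arRP", "sRP", "RP"]},
  "LRAT": {"inheritance": "recessive", "phenotypes": ["LCA", "arRP", "sRP", "RP"]},
  "CNGB3": {"inheritance": "recessive", "phenotypes": ["COD", "ACH", "STGD"]},
  "FSCN2": {"inheritance": "dominant", "phenotypes": ["RP", "arRP", "sRP"]},
  "CRB1": {"inheritance": "recessive", "phenotypes": ["LCA", "arRP", "sRP", "RP"]},
  "RPE65": {"inheritance": "recessive", "phenotypes": ["LCA", "arRP", "sRP", "RP"]},
  "EYS": {"inheritance": "recessive", "phenotypes": ["arRP", "sRP", "RP"]},
  "PDE6B": {"inheritance": "recessive", "phenotypes": ["arRP", "sRP", "RP"]},
  "RHO": {"inheritance": "dominant", "phenotypes": ["RP", "arRP", "sRP"]},
  "CRX": {"inheritance": "dominant", "phenotypes": ["COD", "LCA"]},
  "PRPF31": {"inheritance": "dominant", "phenotypes": ["RP", "arRP", "sRP"]},
  "MYO7A": {"inheritance": "recessive", "phenotypes": ["USH", "arRP", "sRP"]},
  "CDH23": {"inheritance": "recessive", "phenotypes": ["USH", "arRP"]},
  "CERKL": {"inheritance": "recessive", "phenotypes": ["arRP", "sRP", "RP"]}
}
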