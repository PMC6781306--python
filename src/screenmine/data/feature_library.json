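{
  "_comment": "Structural feature library for TRPA1-inhibitor SAR mining. BM = Bemis-Murcko carbon skeletons, PR = plain rings / plain ring systems, MCR = most central rings (canonical SMILES); AG = Kier-Hall E-state atom groups (khs descriptor names). scoring_features lists the features that earn one graph-mining point each.",
  "bm": {
    "BM-1": "C1CCC2CCCCC2C1CCCC1CCC(C1)C1CCCCC1",
    "BM-2": "C1(CCCC1)(C1CCCCC1)CCCC(C1CCCCC1)CC1CCCCC1",
    "BM-3": "C1CCC2CCCC2C1CCCC1CCC(C1)C1CCCCC1"
  },
  "pr": {
    "PR-1": "O=C1NC(=O)c2ccccc2N1",
    "PR-2": "O=C1NC(=O)c2cccnc2N1",
    "PR-3": "O=C1NC(=O)c2ccsc2N1",
    "PR-4": "O=C1NC(=O)c2ccoc2N1",
    "PR-5": "O=C1NC(=O)c2scnc2N1",
    "PR-6": "c1ccccc1",
    "PR-7": "C1CCCC1",
    "PR-8": "c1cscn1"
  },
  "mcr": {
    "MCR-1": "c1cscn1"
  },
  "ag": {
    "AG-1": "khs.ssCH2",
    "AG-2": "khs.dssC",
    "AG-3": "khs.aaaC",
    "AG-4": "khs.ssssC",
    "AG-5": "khs.dsN",
    "AG-6": "khs.aaN",
    "AG-7": "khs.aasN",
    "AG-8": "khs.sOH",
    "AG-9": "khs.dO",
    "AG-10": "khs.aaO",
    "AG-11": "khs.sF",
    "AG-12": "khs.aaS",
    "AG-13": "khs.sCl"
  },
  "scoring_features": [
    "MCR-1", "PR-1", "PR-3", "PR-6", "PR-7", "PR-8",
    "AG-4", "AG-5", "AG-7", "AG-8", "AG-10", "AG-12"
  ]
}
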