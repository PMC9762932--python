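{
  "name": "project_mine",
  "genes": {
    "ANG": "het_reportable",
    "ATXN2": "het_reportable",
    "C21orf2": "het_reportable",
    "C9orf72": "het_reportable",
    "CHCHD10": "het_reportable",
    "DAO": "het_reportable",
    "DCTN1": "het_reportable",
    "FUS": "het_reportable",
    "HNRNPA1": "het_reportable",
    "MATR3": "het_reportable",
    "MOBP": "het_reportable",
    "NEK1": "het_reportable",
    "OPTN": "het_reportable",
    "PFN1": "het_reportable",
    "SCFD1": "het_reportable",
    "SOD1": "het_reportable",
    "SQSTM1": "het_reportable",
    "TAF15": "het_reportable",
    "TARDBP": "het_reportable",
    "TBK1": "het_reportable",
    "TUB4A": "het_reportable",
    "UBQLN2": "het_reportable",
    "VAPB": "het_reportable",
    "VCP": "het_reportable"
  }
}
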