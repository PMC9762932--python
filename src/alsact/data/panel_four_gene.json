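{
  "name": "four_gene",
  "genes": {
    "C9orf72": "het_reportable",
    "FUS": "het_reportable",
    "SOD1": "het_reportable",
    "TARDBP": "het_reportable"
  }
}
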