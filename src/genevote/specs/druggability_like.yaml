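# Druggability-flavored synthetic study: planted effects on plasma-membrane
# localization, regulatory betweenness (inbetreg) and enzyme in-degree
# (metin), at a 5% positive prevalence.
n_genes: 2000
seed: 13
beta:
  "Plasma membrane": 3.0
  inbetreg: 1.0
  metin: 1.0
prevalence: 0.05
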