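# Morbidity-flavored synthetic study: planted effects on the number of
# regulating transcription factors (regin), metabolic betweenness (inbetmet)
# and extracellular localization, at a 14% positive prevalence.
n_genes: 2000
seed: 11
beta:
  regin: 3.0
  inbetmet: 1.0
  "Extracellular space": 1.0
prevalence: 0.14
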