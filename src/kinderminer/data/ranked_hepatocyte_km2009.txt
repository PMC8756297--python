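# Top 20 transcription factors for key phrase "hepatocyte",
# corpus censored through 2009, threshold 1e-5, ratio-ranked.
HNF4A
HNF1A
HNF1B
TCF2
TCF1
FOXA3
NR1I3
NR0B2
FOXA2
NR1I2
NR1H4
IPF1
FOXA1
FOXF1
PBX2
NEUROD1
PROX1
ALF
PAX4
FOXO1A
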