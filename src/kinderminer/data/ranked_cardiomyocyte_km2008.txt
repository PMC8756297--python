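# Top 20 transcription factors for key phrase "cardiomyocyte",
# corpus censored through 2008, threshold 1e-5, ratio-ranked.
GATA4
NKX2-5
TBX18
HDAC9
TBX20
NFATC4
GATA5
TBX5
ISL1
HAND2
MEF2C
NFATC3
HDAC5
FOXO3A
GATA6
MEF2A
ILK
SRF
STAT3
MSC
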