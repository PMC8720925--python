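# Genes reported to interact directly with montelukast, aggregated from
# DGIdb, DSigDB and STITCH. The symbol "SLCO2B" is kept exactly as published
# (it is most likely a truncation of SLCO2B1; we do not silently correct it).
ABCC1
AHR
ALOX5
ATAD5
ATG4B
CCL11
CYP2C8
CYSLTR1
CYSLTR2
IL13
IL4
IL5
KDM4A
LTA4H
LTB4R
LTB4R2
LTC4S
PLA2G1B
POLH
POLI
POLK
PPP1CA
S1PR1
S1PR3
S1PR4
SLCO2B
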