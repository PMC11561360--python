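# Synthetic demo curation table (wide dialect) for the OligoScore engine.
# Scores are illustrative, built around well-known oligodendrogenesis
# regulators and markers; they are NOT the full curated resource.
# Blank cells mean "not curated". Scale: +/-1 (low) to +/-3 (strong).
gene,specification,proliferation,migration,survival,differentiation,myelination,remyelination
OLIG2,3,1,,,2,1,1
SOX10,2,,,1,3,2,1
OLIG1,1,,,,2,2,2
SOX8,1,,,,1,,
NKX2-2,2,,,,2,,
ASCL1,2,1,,,1,,1
MYT1,,1,,,2,,
SOX2,,2,,,-1,,
CHD7,,,,2,2,,1
PDGFRA,,2,1,2,,,
CSPG4,,1,1,,,,
CNP,,,,,1,1,
MAG,,,,,,2,
MBP,,,,,1,3,1
MOG,,,,,,1,
PLP1,,,,,1,3,1
MYRF,,,,,3,3,2
LINGO1,,,,,-2,-2,-1
ID2,,1,,,-2,,
HES5,,1,,,-2,,
BMP4,-2,,,,-2,,
TNF,,,,-2,-2,,1
TLR2,,,,,-1,,-2
IFNG,,,,-2,-2,,-1
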