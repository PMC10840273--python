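# Common-commensal organism classification list (one species-level code per
# line, '#' starts a comment). This is configuration, not code: replace it
# with your surveillance programme's current contaminant list. The entries
# below are a representative subset of organisms conventionally classified
# as common skin commensals in bloodstream-infection surveillance.
STAPHYLOCOCCUS_EPIDERMIDIS
STAPHYLOCOCCUS_HOMINIS
STAPHYLOCOCCUS_CAPITIS
STAPHYLOCOCCUS_HAEMOLYTICUS
STAPHYLOCOCCUS_WARNERI
CUTIBACTERIUM_ACNES
CORYNEBACTERIUM_SPP
BACILLUS_SPP
MICROCOCCUS_SPP
AEROCOCCUS_VIRIDANS
STREPTOCOCCUS_MITIS
STREPTOCOCCUS_ORALIS
STREPTOCOCCUS_SALIVARIUS
LACTOBACILLUS_SPP
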