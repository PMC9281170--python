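gene_symbol,category,species,evidence,source,antibody_registry_id,vendor_link
CR2,Flow,human,validated,curated,,
CD72,Flow,human,validated,curated,,
CD22,Flow,human,validated,curated,,
IGHD,Flow,human,validated,curated,,
CD19,Flow,human,validated,curated,,
TNFRSF13C,Flow,human,validated,curated,,
MS4A1,Flow,human,validated,curated,,
NT5E,Flow,human,validated,curated,,
ICOSLG,Flow,human,validated,curated,,
IGHM,Flow,human,validated,curated,,
IL3RA,Flow,human,validated,curated,,
NRP1,Flow,human,validated,curated,,
NGFR,Flow,human,validated,curated,,
CD8A,Flow,human,validated,curated,,
CD8B,Flow,human,validated,curated,,
CD4,Flow,human,validated,curated,,
FCGR1A,Flow,human,validated,curated,,
ITGAM,Flow,human,validated,curated,,
PVR,Flow,human,validated,curated,,
CD14,Flow,human,validated,curated,,
FCGR3A,Flow,human,validated,curated,,
NCAM1,Flow,human,validated,curated,,
NCR1,Flow,human,validated,curated,,
KIR2DL3,Flow,human,validated,curated,,
IL2RB,Flow,human,validated,curated,,
NCR3,Flow,human,validated,curated,,
CD19,IHC,human,validated,curated,,
MS4A1,IHC,human,validated,curated,,
CD4,IHC,human,validated,curated,,
Vcam1,Flow_Mouse,mouse,homology,curated,,
Pdgfra,Flow_Mouse,mouse,homology,curated,,
Pdgfrb,Flow_Mouse,mouse,homology,curated,,
Cd63,Flow_Mouse,mouse,homology,curated,,
Ptprc,Flow_Mouse,mouse,homology,curated,,
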