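# Epigenetic-enzyme (chromatin writer/reader/eraser/editor) gene symbols
# with family labels.  Placeholder list of the genes named in the study's
# main text; the full curated list has 212 entries.
DNMT1	DNMT
DNMT3A	DNMT
DNMT3B	DNMT
DNMT3L	DNMT
UHRF1	DNMT
TET1	TET
TET2	TET
TET3	TET
TDG	TET
IDH1	IDH
IDH2	IDH
MBD1	MBD
MBD2	MBD
MBD3	MBD
MBD4	MBD
MECP2	MBD
ZBTB4	ZBTB
ZBTB33	ZBTB
ZBTB38	ZBTB
HDAC1	HDAC
HDAC2	HDAC
HDAC3	HDAC
HDAC4	HDAC
HDAC5	HDAC
HDAC6	HDAC
HDAC7	HDAC
HDAC8	HDAC
HDAC9	HDAC
HDAC10	HDAC
HDAC11	HDAC
SIRT1	HDAC
SIRT2	HDAC
SIRT3	HDAC
SIRT6	HDAC
SIRT7	HDAC
KAT2B	HAT
KAT5	HAT
NCOA1	HAT
NCOA2	HAT
NCOA4	HAT
NCOA7	HAT
EZH1	KMT
EZH2	KMT
WHSC1	KMT
SETD2	KMT
SETD3	KMT
SETBP1	KMT
SUV39H1	KMT
SUV39H2	KMT
PRDM2	KMT
PRDM5	KMT
EHMT2	KMT
PRMT1	PRMT
PRMT5	PRMT
KDM1A	KDM
KDM2A	KDM
KDM3A	KDM
KDM4A	KDM
KDM5A	KDM
KDM6A	KDM
KDM6B	KDM
CHD1	CHD
CHD3	CHD
CHD4	CHD
SMARCB1	remodeler
RAD54L	remodeler
TTF2	remodeler
CBX7	PcG
PCNA	replication
EYA4	phosphatase
DUSP1	phosphatase
SMEK3P	phosphatase
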