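# Curated seed-gene lists: class_label <TAB> comma-separated gene symbols
RTT_CLASSICAL	MECP2
RTT_ATYPICAL	MECP2, CDKL5, FOXG1, NTNG1
RTTL_COHORT	KCNQ2, GABRG2, GRIN1, ATP1A2, KCNB1, GRIN2A, TCF4, SEMA6B
RTTL_LITERATURE	ADAM23, AGAP6, ANKRD31, BTBD9, CHRNA5, CLCN5, CREB1, DEAF1, EEF1A2, EIF2B2, EIF4G1, GABBR2, GABRG2, GABRB2, GABRD, GNAO1, GRIN1, GRIN2A, GRIN2B, HCN1, HDAC8, HECW2, HTT, IQSEC2, JMJD1C, KAT6A, KCNB1, KCNQ2, KIF1A, KLF7, MAP2, MBD2, MEF2C, MEIS2, MFSD8, MGRN1, PDLIM7, PTPN4, RHOBTB2, SATB2, SCN1A, SCN2A, SCN8A, SHANK3, SHROOM4, SLC35A2, SLC6A1, SMARCA1, ST3GAL5, STXBP1, SYNGAP1, TBL1XR1, TCF4, VASH2, WDR45, ZFX, ZNF238, ZNF620
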