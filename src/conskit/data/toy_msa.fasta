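>query
MKTLLVAGSEWSIDRA-TPLFHGQNVECARKL
>homolog_001
MKTLL-AGSEWCIDRAETP-F-GQNVECA-KL
>homolog_002
M-TL-VAGSEMCIDRAVTPLFHGQNVECARKL
>homolog_003
MGTLLV-GSEWCIDRK-TPLFHGQPVECARKL
>homolog_004
MKTLLVAGSEWSIDR--TP-FHGQNVECARKL
>homolog_005
MK-LL-AGSEWCIDRA-TPLF-GQN-EC-R-R
>homolog_006
FKTLL-AGSEWSIDRAGTPLFHGQNV-C-RKL
>homolog_007
MKTLLVAGSE--IDRA-TPLFHGQNV-CLRKL
>homolog_008
MKTLLVAGS-WCIDRA-TPLFHGQNVECARKL
>homolog_009
MKTLLVAGS-WCIDRA-TPLFHGQNVECARKL
>homolog_010
MKTLLVAGS-WCIDRA-TPLFHGQNVECVRKL
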