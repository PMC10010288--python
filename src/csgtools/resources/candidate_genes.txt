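# Default 20-gene candidate panel for cGAS-STING signature selection.
# The eight signature genes (activator set STING1/CGAS/IFI16/ATM, response
# set CCL5/CXCL9/CXCL10/CXCL11) are fixed; the remaining twelve are
# pathway-adjacent placeholders (sensing, signalling, NF-kB arms, DNA
# damage response) and are expected to be replaced with a curated list
# via --candidates when one is available.
STING1
CGAS
IFI16
ATM
CCL5
CXCL9
CXCL10
CXCL11
TBK1
IRF3
IRF7
TREX1
ENPP1
MRE11
XRCC5
XRCC6
PRKDC
NFKB1
NFKB2
TP53
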