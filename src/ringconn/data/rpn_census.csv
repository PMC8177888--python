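cluster,count
DMS,4
IPCs,14
DH44,6
CRZ,6
ITP,8
CA-LP,6
PTTH,4
HugRG,4
CAPA,2
EH,2
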