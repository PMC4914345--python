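cell_line	group
BT20	BLBC
HCC1143	BLBC
MDA468	BLBC
MCF7	non-BLBC
T47D	non-BLBC
ZR751	non-BLBC
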