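cancer_type	n_total	n_positive
ESCC	404	66
HNSCC	402	58
CRC	164	22
HCC	158	22
LC	79	7
GC	80	12
BC	132	0
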