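# van der Waals collision radii per element (nm), version 1 (Bondi scale)
element	radius_nm
H	0.120
C	0.170
N	0.155
O	0.152
S	0.180
P	0.180
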