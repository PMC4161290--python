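# intrinsic gas-phase basicities per ionizable-site kind, version 1
# basic sites: GB of the neutral side chain / N-terminal amine
# acidic sites: GB of the carboxylate conjugate base (site neutral when protonated)
kind	gb_kj_per_mol
N-term	886.6
R	1006.6
K	951.0
H	950.2
Q	937.8
C-term	1400.0
D	1428.0
E	1448.0
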