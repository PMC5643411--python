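reagent,cost_gbp_per_sample
Ampure beads,0.87
Bovine serum albumin,0.00
Cyber green,0.02
DNa away,0.12
dNTPs,0.14
Ethanol,0.00
Ligation oligo (HPLC),0.01
Lowbind tubes,0.36
Mini elute kit,1.22
oligos,0.09
Phusion polymerase,1.04
Pipette tips,0.97
Qubit reagents,0.72
Q-PCR stripes,0.21
Qubit tubes,0.19
RNA ligase reaction buffer (+PEG/ATP),0.32
Rnase away,0.04
RNAse-free water,0.02
RNAsin,0.70
Rox,0.03
RQ1 DNase,0.04
Superscript III RT mix,4.26
T4 RNA ligase,0.06
Tapestation reagents,0.53
Tapestation ScreenTapes,1.55
TapeStation Tips,0.18
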