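codon,W
AAA,0.16687487710717608
AAC,0.24972764295820138
AAG,1.0
AAT,1.0
ACA,0.4295390362461291
ACC,0.7736213244976538
ACG,1.0
ACT,0.28344974974574666
AGA,0.5420652227780833
AGC,0.3607109568160507
AGG,0.5176278468403764
AGT,0.25543935588992295
ATA,1.0
ATC,0.6669752239733385
ATG,1.0
ATT,0.8941921143275706
CAA,0.841922309511352
CAC,0.18256834006417638
CAG,1.0
CAT,1.0
CCA,0.9454018363190891
CCC,0.41590372268797365
CCG,1.0
CCT,0.06594073998264767
CGA,0.6698366695921472
CGC,0.6209205609483088
CGG,0.8008897232345114
CGT,1.0
CTA,0.4182790960356655
CTC,0.8663095473029587
CTG,1.0
CTT,0.49806658553786787
GAA,0.5048454997637479
GAC,1.0
GAG,1.0
GAT,0.19862017901861395
GCA,0.15894584013322258
GCC,0.0803864407231372
GCG,1.0
GCT,0.17758097593522432
GGA,1.0
GGC,0.6384414905147376
GGG,0.6721442912099214
GGT,0.516391262314017
GTA,0.057406631725191816
GTC,0.1421571276766047
GTG,0.5409745389444222
GTT,1.0
TAC,1.0
TAT,0.6073957311473708
TCA,0.06428216648566179
TCC,0.3898145429132156
TCG,0.4986694426851144
TCT,1.0
TGC,1.0
TGG,1.0
TGT,0.5041855723554038
TTA,0.24318790741048124
TTC,0.763194697440939
TTG,0.44649571508974345
TTT,1.0
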