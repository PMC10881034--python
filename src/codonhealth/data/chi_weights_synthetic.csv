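codon,W
AAA,0.7931441133763255
AAC,0.5987172470394502
AAG,1.0
AAT,1.0
ACA,1.0
ACC,0.92445095550685
ACG,0.3149644439256353
ACT,0.47603792419684826
AGA,0.17112018445403304
AGC,0.15487402079994086
AGG,0.8464817965196577
AGT,0.39833349212467456
ATA,0.38024758988379354
ATC,0.5922860901306013
ATG,1.0
ATT,1.0
CAA,1.0
CAC,0.6838062672072545
CAG,0.7036034907669895
CAT,1.0
CCA,0.06311456205385914
CCC,1.0
CCG,0.6140807979587688
CCT,0.238435872943571
CGA,0.5660938364443739
CGC,0.5068029951130681
CGG,1.0
CGT,0.8826789210892947
CTA,0.23211492224875732
CTC,0.5199286207971638
CTG,0.4727635810971845
CTT,0.5131383809559332
GAA,0.12609417365680364
GAC,1.0
GAG,1.0
GAT,0.07252213968423635
GCA,1.0
GCC,0.7975023513202002
GCG,0.6938061734366268
GCT,0.2855329250859949
GGA,0.5787875814220091
GGC,0.9113317852196575
GGG,1.0
GGT,0.86274630368919
GTA,0.5719920735389519
GTC,0.8320913130331584
GTG,1.0
GTT,0.21415949837014037
TAC,0.1096444641883761
TAT,1.0
TCA,0.23016533756691113
TCC,0.49532908486932276
TCG,1.0
TCT,0.8841729449017608
TGC,0.4012104093065499
TGG,1.0
TGT,1.0
TTA,0.13381058540006133
TTC,1.0
TTG,1.0
TTT,0.35003779248451583
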