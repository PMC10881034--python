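codon,time
AAA,0.12239956031828608
AAC,0.19044896353619245
AAG,0.05
AAT,0.05
ACA,0.05
ACC,0.07644216557260251
ACG,0.2897624446260277
ACT,0.23338672653110315
AGA,0.3401079354410884
AGC,0.3457940927200207
AGG,0.1037313712181198
AGT,0.26058327775636386
ATA,0.26691334354067225
ATC,0.19269986845428955
ATG,0.05
ATT,0.05
CAA,0.05
CAC,0.16066780647746093
CAG,0.15373877823155369
CAT,0.05
CCA,0.3779099032811493
CCC,0.05
CCG,0.18507172071443093
CCT,0.3165474444697502
CGA,0.20186715724446913
CGC,0.22261895171042614
CGG,0.05
CGT,0.09106237761874686
CTA,0.31875977721293497
CTC,0.2180249827209927
CTG,0.23453274661598542
CTT,0.22040156666542338
GAA,0.35586703922011875
GAC,0.05
GAG,0.05
GAT,0.3746172511105173
GCA,0.05
GCC,0.12087417703792994
GCG,0.15716783929718064
GCT,0.3000634762199018
GGA,0.19742434650229682
GGC,0.08103387517311987
GGG,0.05
GGT,0.09803879370878349
GTA,0.19980277426136683
GTC,0.10876804043839457
GTG,0.05
GTT,0.3250441755704509
TAA,0.05
TAC,0.36162443753406837
TAG,0.05
TAT,0.05
TCA,0.3194421318515811
TCC,0.22663482029573703
TCG,0.05
TCT,0.09053946928438372
TGA,0.05
TGC,0.25957635674270757
TGG,0.05
TGT,0.05
TTA,0.35316629510997855
TTC,0.05
TTG,0.05
TTT,0.2774867726304195
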