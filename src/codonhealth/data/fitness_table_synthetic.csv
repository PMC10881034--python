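codon,c,m,is_parent
AAA,0.3556464093270173,1.0638001695336556,0
AAG,1.0,1.0,1
AAC,0.28149659887640727,0.7985514063765783,0
AAT,1.0,1.0,1
ACA,1.0,1.0,1
ACC,0.7755465225420449,1.05249547725774,0
ACG,0.1671607411029502,0.4128710313265897,0
ACT,0.09321905105311189,0.6667341442194527,0
AGA,0.21195995055865277,0.1167784843810625,0
AGG,0.8768051190110181,0.8150310711588662,0
CGA,0.7684007703035125,0.2246880493430571,0
CGC,0.18264191571787788,0.6930660014270336,0
CGG,1.0,1.0,1
CGT,0.7895026384458097,0.9669176486949795,0
AGC,0.1532609790521372,0.15647043470720404,0
AGT,0.11331655131517133,0.5518138282922171,0
TCA,0.08585339999676561,0.3139766853503229,0
TCC,0.6770050663001723,0.1799053774595435,0
TCG,1.0,1.0,1
TCT,1.009960442018034,0.7372268976042872,0
ATA,0.50049758869688,0.19666881535585673,0
ATC,0.5964847689725608,0.5880574338516098,0
ATT,1.0,1.0,1
ATG,1.0,1.0,1
CAA,1.0,1.0,1
CAG,0.1979402008304106,0.9751591774342294,0
CAC,0.7964962070943273,0.5484303184801044,0
CAT,1.0,1.0,1
CCA,0.05364979396486944,0.07133439208423895,0
CCC,1.0,1.0,1
CCG,0.4782465815590822,0.7248935508544746,0
CCT,0.1543006116030825,0.2998243690423448,0
CTA,0.1589414986440329,0.28721468324213895,0
CTC,0.164580445239229,0.7166343687634157,0
CTG,0.6637826138250486,0.08002155214224993,0
CTT,0.4166980755411202,0.5941251634634573,0
TTA,0.1752412569429508,0.0714216171426334,0
TTG,1.0,1.0,1
GAA,0.16577597132466043,0.06571003417857636,0
GAG,1.0,1.0,1
GAC,1.0,1.0,1
GAT,0.07028777669156128,0.07468969096546721,0
GCA,1.0,1.0,1
GCC,0.8298903148270237,0.7637421463287201,0
GCG,0.6797843219183606,0.7075502019443879,0
GCT,0.39338593024745033,0.09113513317967416,0
GGA,0.7830113843958886,0.23850220276364714,0
GGC,1.2588966774070356,0.2760985351587771,0
GGG,1.0,1.0,1
GGT,1.2091202304355542,0.16337269481217742,0
GTA,0.4760684422370665,0.6539944209920697,0
GTC,0.3838455786679365,1.112391333204088,0
GTG,1.0,1.0,1
GTT,0.14259345687114472,0.2671997147113696,0
TAC,0.139029016412591,0.0686640346153624,0
TAT,1.0,1.0,1
TGC,0.3502945188581239,0.44635561509833627,0
TGT,1.0,1.0,1
TGG,1.0,1.0,1
TTC,1.0,1.0,1
TTT,0.07832734214980991,0.488792123306639,0
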