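marker,location,habitat,strain,accession,substitutions,dissimilarity_percent
SSU,Australia,Hypersaline,CCAP 19/18,EF473745,0,0
SSU,Israel,Hypersaline,SAG 42.88,EF473740,0,0
SSU,Israel,Brackish,CCAP 19/12,KJ756842,0,0
SSU,Republic of Korea,Hypersaline,KMMCC 1428,JQ315781,0,0
SSU,ND,ND,GY-H13,MN832905,0,0
SSU,Mexico,Hypersaline,UTEX LB 1644,DQ009765,2,0.1
SSU,Thailand,soil,KU07,KF825551,7,0.5
rbcL,China,ND,OUC66,DQ173086,0,0
rbcL,China,ND,OUC36,DQ173084,0,0
rbcL,Inner Mongolia,ND,Inner Mongolia,DQ173087,0,0
rbcL,China,ND,OUC38,DQ173085,0,0
rbcL,ND,ND,TS-1,AB127990,0,0
rbcL,USA,ND,UTEX2538,DQ313194,0,0
rbcL,Republic of Korea,ND,KMMCC1346,JQ315489,0,0
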